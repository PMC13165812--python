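# atompool

Interpretable hierarchical graph pooling for graph classification via atomic
decomposition. Each graph is decomposed into recurring structural "atoms":
per-node ego-networks (center plus up to S−1 highest-degree neighbors) are
vectorized into a binary sampling matrix, which a greedy Boolean matrix
factorization splits into a dictionary of atom patterns and a sparse code.
Atom/node co-occurrence counts, normalized per node and per column, yield a
column-stochastic assignment matrix `S` that coarsens the graph
(`X' = S X`, `A' = S A Sᵀ`). A small graph-convolution network stacks two such
pooling steps between three convolution layers, concatenates
max/mean/sum readouts of every stage, and classifies with a two-layer MLP.
Because atoms are explicit subgraph patterns, the pooling decisions are
directly inspectable: per-atom, per-class activation-proportion tables report
which substructures drive each class.

The network (propagation rule, backpropagation, Adam, early stopping,
stratified cross-validation) is implemented in dense numpy — no deep-learning
framework required; graphs at this scale are small.

## Layout

| module | contents |
| --- | --- |
| `atompool.graph_io` | `Graph`/`GraphDataset` model, TU flat-file reader/writer, one-hot features |
| `atompool.ego` | `PoolingConfig`, ego-network sampling, sampling-matrix construction |
| `atompool.bmf` | greedy Boolean matrix factorization (association candidates, coverage objective) |
| `atompool.pooling` | affiliation matrix, assignment matrix, coarsening, `pool_layer` |
| `atompool.network` | GCN + pooling classifier, training, 10-fold CV, atom report |
| `atompool.synthetic` | motif-planted graph/dataset generators with ground truth |
| `atompool.cli` | `atompool` command-line entry point |

## CLI

```bash
# two-class motif-planted dataset in TU flat-file format
atompool make-synthetic --out-dir data/ --name SYN --graphs-per-class 100 \
    --class0-motif clique4 --class1-motif star5 --noise 0.02 --seed 0

# factorize one graph's sampling matrix into atoms
atompool extract-atoms --data-dir data/ --dataset SYN --graph-index 0 \
    --ego-size 5 --phi 0.6 --out atoms.txt

# one pooling step: dumps S, D, C, A', X' as text matrices
atompool pool --data-dir data/ --dataset SYN --graph-index 0 --out-dir pooled/

# cross-validated training (defaults: hidden 128, lr 0.001, wd 5e-4,
# batch 64, 500 epochs, patience 50, 10 folds, pooling ratio 0.5)
atompool train --data-dir data/ --dataset SYN --epochs 100 --seed 1 \
    --report run.json

# per-atom class activation-proportion table
atompool report-atoms --data-dir data/ --dataset SYN --out atoms.csv
```

Real TU-format benchmark directories (e.g. `DD_A.txt`, …) load the same way
via `--data-dir <dir> --dataset DD`; there is no built-in downloader.

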