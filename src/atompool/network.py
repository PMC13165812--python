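"""Graph classification network built around the atomic pooling layer.

A stack of graph-convolution layers (symmetric-normalized propagation with
self-loops, ReLU) interleaved with combinatorial pooling steps.  Pooling
assignments are computed once per graph from topology alone and enter the
forward pass as constants, so gradients flow through S·X while S itself is
fixed.  The graph representation concatenates a [max ‖ mean ‖ sum] readout
of every convolution stage and feeds a two-layer MLP classifier.

Everything is dense numpy with hand-written backpropagation and Adam; graphs
in these benchmarks are small enough that this is faster than it sounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .bmf import AtomDictionary
from .ego import PoolingConfig, devectorize_ego
from .graph_io import Graph, GraphDataset
from .pooling import PoolResult, pool_layer

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "GraphCache",
    "build_graph_cache",
    "normalized_adjacency",
    "gcn_propagate",
    "readout",
    "init_params",
    "forward",
    "train_model",
    "evaluate",
    "cross_validate",
    "CVResult",
    "atom_report",
    "atom_adjacency",
    "atom_edge_list",
]


@dataclass(frozen=True)
class ModelConfig:
    hidden_dim: int = 128
    mlp_hidden: int = 64
    conv_layers: int = 3
    pool_after: tuple[int, ...] = (1, 2)
    dropout: float = 0.5
    backbone: str = "gcn"

    def __post_init__(self) -> None:
        if not set(self.pool_after) <= set(range(1, self.conv_layers)):
            raise ValueError(
                f"pool_after {self.pool_after} must be a subset of "
                f"{{1..{self.conv_layers - 1}}}"
            )
        if self.backbone not in ("gcn", "gat"):
            raise ValueError("backbone must be 'gcn' or 'gat'")
        if self.backbone == "gat":
            raise NotImplementedError("gat backbone is a registered seam only")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def embedding_dim(self) -> int:
        return 3 * self.hidden_dim * self.conv_layers


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 5e-4
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 50
    seed: int = 0
    folds: int = 10

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


@dataclass
class GraphCache:
    """Per-graph constants: features, label, and per-layer propagation data.

    ``ahats[l]`` is the normalized adjacency the l-th convolution runs on;
    ``s_after[l]`` is the assignment matrix applied after that convolution
    (None when no pooling follows the layer).
    """

    features: np.ndarray
    label: int
    ahats: list[np.ndarray]
    s_after: list[np.ndarray | None]
    pool_results: list[PoolResult] = field(default_factory=list)

    @property
    def node_counts(self) -> list[int]:
        return [a.shape[0] for a in self.ahats]


def normalized_adjacency(a: np.ndarray) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} with D the degree matrix of A + I."""
    a = np.asarray(a, dtype=float)
    a_tilde = a + np.eye(a.shape[0])
    d = a_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_propagate(x: np.ndarray, a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One convolution: ReLU(norm(A) X W); supports weighted A."""
    return np.maximum(normalized_adjacency(a) @ np.asarray(x, dtype=float) @ w, 0.0)


def readout(x: np.ndarray) -> np.ndarray:
    """[columnwise max ‖ mean ‖ sum], length 3d."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("readout needs at least one node")
    return np.concatenate([x.max(axis=0), x.mean(axis=0), x.sum(axis=0)])


def _readout_backward(dr: np.ndarray, x: np.ndarray) -> np.ndarray:
    n, d = x.shape
    d_max, d_mean, d_sum = dr[:d], dr[d : 2 * d], dr[2 * d :]
    dx = np.tile(d_mean / n + d_sum, (n, 1))
    dx[x.argmax(axis=0), np.arange(d)] += d_max
    return dx


def build_graph_cache(
    graph: Graph, mcfg: ModelConfig, pcfg: PoolingConfig
) -> GraphCache:
    """Precompute normalized adjacencies and pooling assignments for one graph."""
    a_cur = np.asarray(graph.adjacency, dtype=float)
    ahats: list[np.ndarray] = []
    s_after: list[np.ndarray | None] = []
    pool_results: list[PoolResult] = []
    for layer in range(1, mcfg.conv_layers + 1):
        ahats.append(normalized_adjacency(a_cur))
        if layer in mcfg.pool_after:
            res = pool_layer(a_cur, np.ones((a_cur.shape[0], 1)), pcfg)
            s_after.append(res.assignment.matrix)
            pool_results.append(res)
            a_cur = res.coarsened.adjacency
        else:
            s_after.append(None)
    return GraphCache(
        features=np.asarray(graph.features, dtype=float),
        label=int(graph.label) if graph.label is not None else -1,
        ahats=ahats,
        s_after=s_after,
        pool_results=pool_results,
    )


def init_params(
    in_dim: int, n_classes: int, mcfg: ModelConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases."""

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    params: dict[str, np.ndarray] = {}
    dim = in_dim
    for l in range(mcfg.conv_layers):
        params[f"W{l}"] = glorot(dim, mcfg.hidden_dim)
        dim = mcfg.hidden_dim
    params["Wm1"] = glorot(mcfg.embedding_dim, mcfg.mlp_hidden)
    params["bm1"] = np.zeros(mcfg.mlp_hidden)
    params["Wm2"] = glorot(mcfg.mlp_hidden, n_classes)
    params["bm2"] = np.zeros(n_classes)
    return params


def forward(
    cache: GraphCache,
    params: dict[str, np.ndarray],
    mcfg: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
    keep: bool = False,
) -> np.ndarray | tuple[np.ndarray, dict]:
    """Class logits for one graph; with ``keep`` also the backprop tape."""
    if cache.features.shape[1] != params["W0"].shape[0]:
        raise ValueError(
            f"feature dim {cache.features.shape[1]} does not match model "
            f"input dim {params['W0'].shape[0]}"
        )
    drop = mcfg.dropout if training else 0.0
    if drop > 0 and rng is None:
        raise ValueError("training-mode forward with dropout needs an rng")

    x = cache.features
    tape: dict = {"P": [], "Z": [], "Hd": [], "mask": []}
    reads = []
    for l in range(mcfg.conv_layers):
        p = cache.ahats[l] @ x
        z = p @ params[f"W{l}"]
        h = np.maximum(z, 0.0)
        if drop > 0:
            mask = (rng.random(h.shape) >= drop) / (1.0 - drop)
            hd = h * mask
        else:
            mask = None
            hd = h
        reads.append(readout(hd))
        tape["P"].append(p)
        tape["Z"].append(z)
        tape["Hd"].append(hd)
        tape["mask"].append(mask)
        s = cache.s_after[l]
        x = s @ hd if s is not None else hd
    h_graph = np.concatenate(reads)
    z1 = h_graph @ params["Wm1"] + params["bm1"]
    a1 = np.maximum(z1, 0.0)
    logits = a1 @ params["Wm2"] + params["bm2"]
    if not keep:
        return logits
    tape.update({"h_graph": h_graph, "z1": z1, "a1": a1})
    return logits, tape


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _backward(
    cache: GraphCache,
    params: dict[str, np.ndarray],
    mcfg: ModelConfig,
    tape: dict,
    dlogits: np.ndarray,
    grads: dict[str, np.ndarray],
) -> None:
    """Accumulate parameter gradients for one graph into ``grads``."""
    grads["bm2"] += dlogits
    grads["Wm2"] += np.outer(tape["a1"], dlogits)
    da1 = params["Wm2"] @ dlogits
    dz1 = da1 * (tape["z1"] > 0)
    grads["bm1"] += dz1
    grads["Wm1"] += np.outer(tape["h_graph"], dz1)
    dh_graph = params["Wm1"] @ dz1

    h = mcfg.hidden_dim
    dx_next: np.ndarray | None = None
    for l in reversed(range(mcfg.conv_layers)):
        dr = dh_graph[3 * h * l : 3 * h * (l + 1)]
        dhd = _readout_backward(dr, tape["Hd"][l])
        if dx_next is not None:
            s = cache.s_after[l]
            dhd += s.T @ dx_next if s is not None else dx_next
        if tape["mask"][l] is not None:
            dhd = dhd * tape["mask"][l]
        dz = dhd * (tape["Z"][l] > 0)
        grads[f"W{l}"] += tape["P"][l].T @ dz
        if l > 0:
            dx_next = cache.ahats[l].T @ (dz @ params[f"W{l}"].T)


def _loss_and_grads(
    caches: list[GraphCache],
    params: dict[str, np.ndarray],
    mcfg: ModelConfig,
    rng: np.random.Generator,
) -> tuple[float, dict[str, np.ndarray]]:
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    total = 0.0
    for cache in caches:
        logits, tape = forward(
            cache, params, mcfg, training=True, rng=rng, keep=True
        )
        probs = _softmax(logits)
        total += -np.log(max(probs[cache.label], 1e-12))
        dlogits = probs.copy()
        dlogits[cache.label] -= 1.0
        _backward(cache, params, mcfg, tape, dlogits / len(caches), grads)
    return total / len(caches), grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float):
        self.lr, self.wd = lr, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k] + self.wd * p
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def evaluate(
    caches: list[GraphCache], params: dict[str, np.ndarray], mcfg: ModelConfig
) -> tuple[float, float]:
    """(accuracy, mean cross-entropy) with dropout disabled."""
    correct, loss = 0, 0.0
    for cache in caches:
        probs = _softmax(forward(cache, params, mcfg))
        loss += -np.log(max(probs[cache.label], 1e-12))
        if int(np.argmax(probs)) == cache.label:
            correct += 1
    return correct / len(caches), loss / len(caches)


def train_model(
    train_caches: list[GraphCache],
    val_caches: list[GraphCache],
    n_classes: int,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
) -> tuple[dict[str, np.ndarray], dict]:
    """Adam + early stopping on validation accuracy (loss breaks ties).

    Returns the best-validation parameters and a history dict with per-epoch
    train loss and validation accuracy.
    """
    if not train_caches or not val_caches:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(tcfg.seed)
    in_dim = train_caches[0].features.shape[1]
    params = init_params(in_dim, n_classes, mcfg, rng)
    opt = _Adam(params, tcfg.learning_rate, tcfg.weight_decay)

    best = {"acc": -1.0, "loss": np.inf, "params": None, "epoch": -1}
    history: dict = {"train_loss": [], "val_acc": [], "val_loss": []}
    since_improvement = 0
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(len(train_caches))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), tcfg.batch_size):
            batch = [train_caches[i] for i in order[start : start + tcfg.batch_size]]
            loss, grads = _loss_and_grads(batch, params, mcfg, rng)
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        val_acc, val_loss = evaluate(val_caches, params, mcfg)
        history["train_loss"].append(epoch_loss / n_batches)
        history["val_acc"].append(val_acc)
        history["val_loss"].append(val_loss)
        improved = val_acc > best["acc"] or (
            val_acc == best["acc"] and val_loss < best["loss"]
        )
        if improved:
            best = {
                "acc": val_acc,
                "loss": val_loss,
                "params": {k: v.copy() for k, v in params.items()},
                "epoch": epoch,
            }
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= tcfg.patience:
                break
    history["best_epoch"] = best["epoch"]
    history["best_val_acc"] = best["acc"]
    return best["params"], history


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies))


def stratified_fold_indices(
    labels: np.ndarray, folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified partition of graph indices into ``folds`` parts."""
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} graphs; use at most that many folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(
    dataset: GraphDataset,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    pcfg: PoolingConfig,
    caches: list[GraphCache] | None = None,
) -> tuple[CVResult, list[dict]]:
    """Stratified k-fold evaluation: per fold, one part tests, one validates,
    the rest train (8/1/1 at 10 folds)."""
    labels = dataset.labels
    fold_idx = stratified_fold_indices(labels, tcfg.folds, tcfg.seed)
    if caches is None:
        caches = [build_graph_cache(g, mcfg, pcfg) for g in dataset]
    accs, histories = [], []
    for f in range(tcfg.folds):
        test_idx = fold_idx[f]
        if tcfg.folds >= 3:
            val_idx = fold_idx[(f + 1) % tcfg.folds]
        else:
            # too few folds to donate a whole one: stratified-split the rest
            rest = np.setdiff1d(np.arange(len(dataset)), test_idx)
            sub = stratified_fold_indices(labels[rest], 2, tcfg.seed + f)
            val_idx = rest[sub[0]]
        held = set(test_idx) | set(val_idx)
        train_idx = [i for i in range(len(dataset)) if i not in held]
        params, history = train_model(
            [caches[i] for i in train_idx],
            [caches[i] for i in val_idx],
            dataset.class_count,
            mcfg,
            replace(tcfg, seed=tcfg.seed + f),
        )
        acc, _ = evaluate([caches[i] for i in test_idx], params, mcfg)
        accs.append(acc)
        histories.append(history)
        logger.info("fold %d/%d: test accuracy %.3f", f + 1, tcfg.folds, acc)
    return CVResult(fold_accuracies=tuple(accs)), histories


# ---------------------------------------------------------------------------
# interpretability
# ---------------------------------------------------------------------------


def atom_adjacency(column: np.ndarray, ego_size: int) -> np.ndarray:
    """Reshape a dictionary column to its symmetrized ego-size atom pattern."""
    a = devectorize_ego(np.asarray(column), ego_size)
    a = np.maximum(a, a.T).astype(np.int8)
    np.fill_diagonal(a, 0)
    return a


def atom_edge_list(column: np.ndarray, ego_size: int) -> list[tuple[int, int]]:
    a = atom_adjacency(column, ego_size)
    return [(int(u), int(v)) for u, v in zip(*np.nonzero(np.triu(a)))]


def atom_report(
    dataset: GraphDataset,
    pcfg: PoolingConfig,
    pool_results: list[PoolResult] | None = None,
) -> pd.DataFrame:
    """Per-atom class activation table over first-layer pooling runs.

    Atoms from different graphs are identified by their dictionary column
    pattern.  For each atom and class, the table reports the mean over all
    graphs of that class of the fraction of nodes with a positive assignment
    to the atom (graphs where the atom was not found contribute 0), mirroring
    an activation-proportion interpretability table.
    """
    if pool_results is None:
        pool_results = [
            pool_layer(g.adjacency, g.features, pcfg) for g in dataset
        ]
    per_class_sums: dict[bytes, np.ndarray] = {}
    patterns: dict[bytes, np.ndarray] = {}
    class_sizes = np.bincount(dataset.labels, minlength=dataset.class_count)
    for g, res in zip(dataset, pool_results):
        if res.identity_fallback:
            continue
        s = res.assignment.matrix
        d = res.factorization.dictionary.matrix
        n = g.node_count
        for i in range(d.shape[1]):
            key = d[:, i].tobytes()
            proportion = float(np.count_nonzero(s[i] > 1e-12)) / n
            if key not in per_class_sums:
                per_class_sums[key] = np.zeros(dataset.class_count)
                patterns[key] = d[:, i].copy()
            per_class_sums[key][g.label] += proportion

    rows = []
    for atom_id, (key, sums) in enumerate(
        sorted(per_class_sums.items(), key=lambda kv: -kv[1].sum())
    ):
        edges = atom_edge_list(patterns[key], pcfg.ego_size)
        row = {
            "atom_id": atom_id,
            "edges": ";".join(f"{u}-{v}" for u, v in edges),
            "edge_count": len(edges),
        }
        for cls in range(dataset.class_count):
            row[f"class_{cls}_activation"] = (
                sums[cls] / class_sizes[cls] if class_sizes[cls] else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)
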