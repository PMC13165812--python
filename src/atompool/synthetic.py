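"""Motif-planted synthetic graphs with known ground truth.

Each graph is a disjoint union of small motif copies (cliques, stars, chains,
bipartite blocks), wired together with a few random bridge edges and optional
independent noise edges.  Two-class datasets plant different motif families
per class so that atom-recovery and classification behavior can be checked
against planted ground truth without downloading benchmark data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_io import Graph, GraphDataset, one_hot_features

__all__ = [
    "MotifSpec",
    "SyntheticConfig",
    "MOTIF_LIBRARY",
    "clique_motif",
    "star_motif",
    "chain_motif",
    "bipartite_motif",
    "plant_motif_graph",
    "generate_two_class_dataset",
    "plant_boolean_factors",
]


@dataclass(frozen=True)
class MotifSpec:
    """A named small connected subgraph pattern."""

    name: str
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diagonal(a)):
            raise ValueError("motif adjacency must be symmetric, zero-diagonal")
        if not _is_connected(a):
            raise ValueError(f"motif {self.name!r} must be connected")

    @property
    def size(self) -> int:
        return self.adjacency.shape[0]


def _is_connected(a: np.ndarray) -> bool:
    n = a.shape[0]
    if n == 0:
        return False
    seen = {0}
    frontier = [0]
    while frontier:
        u = frontier.pop()
        for v in np.flatnonzero(a[u]):
            if v not in seen:
                seen.add(int(v))
                frontier.append(int(v))
    return len(seen) == n


def clique_motif(size: int = 4) -> MotifSpec:
    a = np.ones((size, size), dtype=np.int8) - np.eye(size, dtype=np.int8)
    return MotifSpec(name=f"clique{size}", adjacency=a)


def star_motif(size: int = 5) -> MotifSpec:
    """Hub at index 0 with ``size - 1`` leaves."""
    a = np.zeros((size, size), dtype=np.int8)
    a[0, 1:] = a[1:, 0] = 1
    return MotifSpec(name=f"star{size}", adjacency=a)


def chain_motif(size: int = 4) -> MotifSpec:
    a = np.zeros((size, size), dtype=np.int8)
    idx = np.arange(size - 1)
    a[idx, idx + 1] = a[idx + 1, idx] = 1
    return MotifSpec(name=f"chain{size}", adjacency=a)


def bipartite_motif(left: int = 2, right: int = 2) -> MotifSpec:
    size = left + right
    a = np.zeros((size, size), dtype=np.int8)
    a[:left, left:] = 1
    a[left:, :left] = 1
    return MotifSpec(name=f"bipartite{left}x{right}", adjacency=a)


MOTIF_LIBRARY: dict[str, MotifSpec] = {
    m.name: m
    for m in (clique_motif(4), star_motif(5), chain_motif(4), bipartite_motif(2, 2))
}


def plant_boolean_factors(
    m: int, t: int, rank: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted exact Boolean factorization Y = D ∘ C of Boolean rank ``rank``.

    Dictionary columns get pairwise-disjoint row supports and code rows are
    pairwise incomparable (no subset relation) and nonempty, which makes the
    planted columns exactly recoverable by association-candidate greedy
    coverage.  Returns (Y, D, C).
    """
    if rank < 1 or rank > min(m, t):
        raise ValueError("rank must be in [1, min(m, t)]")
    # disjoint supports: random surjective assignment of rows to atoms
    owner = np.concatenate([np.arange(rank), rng.integers(rank, size=m - rank)])
    rng.shuffle(owner)
    d = np.zeros((m, rank), dtype=np.uint8)
    d[np.arange(m), owner] = 1
    # incomparable, distinct, nonempty code rows (rejection sampling)
    rows: list[np.ndarray] = []
    while len(rows) < rank:
        cand = (rng.random(t) < 0.5).astype(np.uint8)
        if not cand.any():
            continue
        ok = all(
            ((cand & r) != cand).any() and ((cand & r) != r).any() for r in rows
        )
        if ok:
            rows.append(cand)
    c = np.stack(rows, axis=0)
    y = np.minimum(d.astype(int) @ c.astype(int), 1).astype(np.uint8)
    return y, d, c


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for a two-class motif-planted dataset.

    ``motifs_per_class`` maps each class index to a list of
    (motif, mean copy count) pairs; copy counts are Poisson-distributed with
    the given mean (floored at one copy).
    """

    motifs_per_class: dict[int, tuple[tuple[MotifSpec, float], ...]]
    graphs_per_class: int = 100
    noise_edge_prob: float = 0.0
    bridge_edges: int = 1
    seed: int = 0
    feature_dim: int | None = None

    def __post_init__(self) -> None:
        if not self.motifs_per_class:
            raise ValueError("need at least one class")
        for cls, motifs in self.motifs_per_class.items():
            if not motifs:
                raise ValueError(f"class {cls} has no motifs")
        if not (0.0 <= self.noise_edge_prob < 1.0):
            raise ValueError("noise_edge_prob must be in [0, 1)")
        if self.bridge_edges < 0:
            raise ValueError("bridge_edges must be >= 0")
        if self.graphs_per_class < 1:
            raise ValueError("graphs_per_class must be >= 1")


def plant_motif_graph(
    motifs: list[tuple[MotifSpec, int]],
    bridge_edges: int,
    noise_edge_prob: float,
    rng: np.random.Generator,
    feature_dim: int | None = None,
    label: int | None = None,
) -> tuple[Graph, list[tuple[str, int]]]:
    """Assemble motif copies, bridges and noise into one graph.

    Returns the graph and a per-node (motif name, copy index) ground-truth
    map.  Node features one-hot encode the node's role (its index inside its
    motif), over an alphabet of size ``feature_dim`` (default: largest motif).
    """
    if not motifs or all(count == 0 for _, count in motifs):
        raise ValueError("need at least one motif copy")
    blocks: list[np.ndarray] = []
    membership: list[tuple[str, int]] = []
    roles: list[int] = []
    copy_spans: list[tuple[int, int]] = []
    offset = 0
    copy_idx = 0
    for spec, count in motifs:
        for _ in range(count):
            blocks.append(np.asarray(spec.adjacency, dtype=np.int8))
            membership.extend((spec.name, copy_idx) for _ in range(spec.size))
            roles.extend(range(spec.size))
            copy_spans.append((offset, offset + spec.size))
            offset += spec.size
            copy_idx += 1
    n = offset
    a = np.zeros((n, n), dtype=np.int8)
    pos = 0
    for block in blocks:
        s = block.shape[0]
        a[pos : pos + s, pos : pos + s] = block
        pos += s

    if len(copy_spans) > 1:
        for _ in range(bridge_edges):
            i, j = rng.choice(len(copy_spans), size=2, replace=False)
            u = int(rng.integers(*copy_spans[i]))
            v = int(rng.integers(*copy_spans[j]))
            a[u, v] = a[v, u] = 1

    if noise_edge_prob > 0:
        iu, ju = np.triu_indices(n, k=1)
        flips = rng.random(len(iu)) < noise_edge_prob
        add = flips & (a[iu, ju] == 0)
        a[iu[add], ju[add]] = 1
        a[ju[add], iu[add]] = 1

    alphabet = feature_dim if feature_dim is not None else (max(r for r in roles) + 1)
    features = one_hot_features(roles, alphabet)
    return Graph(adjacency=a, features=features, label=label), membership


def generate_two_class_dataset(
    config: SyntheticConfig,
) -> tuple[GraphDataset, list[list[tuple[str, int]]]]:
    """Balanced multi-class dataset of motif-planted graphs, seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.motifs_per_class)
    alphabet = config.feature_dim
    if alphabet is None:
        alphabet = max(
            spec.size
            for motifs in config.motifs_per_class.values()
            for spec, _ in motifs
        )

    graphs: list[Graph] = []
    truth: list[list[tuple[str, int]]] = []
    for cls in classes:
        recipe = config.motifs_per_class[cls]
        for _ in range(config.graphs_per_class):
            counts = [
                (spec, max(1, int(rng.poisson(mean)))) for spec, mean in recipe
            ]
            g, members = plant_motif_graph(
                counts,
                bridge_edges=config.bridge_edges,
                noise_edge_prob=config.noise_edge_prob,
                rng=rng,
                feature_dim=alphabet,
                label=classes.index(cls),
            )
            graphs.append(g)
            truth.append(members)

    order = rng.permutation(len(graphs))
    graphs = [graphs[i] for i in order]
    truth = [truth[i] for i in order]
    for i, g in enumerate(graphs):
        g.graph_id = i
    dataset = GraphDataset(
        graphs=graphs,
        class_count=len(classes),
        feature_dim=alphabet,
        name="synthetic",
    )
    return dataset, truth
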