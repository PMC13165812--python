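"""Graph data model and TU flat-file dataset I/O.

The TU benchmark layout is a directory of plain-text files sharing a dataset
name prefix::

    <name>_A.txt               one "u, v" edge per line, 1-based global node ids
    <name>_graph_indicator.txt graph id (1-based) of node i on line i
    <name>_graph_labels.txt    class label of graph g on line g
    <name>_node_labels.txt     optional discrete node label per node
    <name>_node_attributes.txt optional comma-separated real vector per node

Internally everything is 0-based; conversion happens only at this boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "GraphDataset",
    "TUFormatError",
    "GraphIntegrityError",
    "read_tu_dataset",
    "write_tu_dataset",
    "one_hot_features",
]


class TUFormatError(Exception):
    """A mandatory dataset file is missing or malformed."""


class GraphIntegrityError(Exception):
    """The dataset violates a structural constraint (e.g. cross-graph edge)."""


@dataclass
class Graph:
    """An undirected graph with node features and an optional class label.

    ``adjacency`` is a dense symmetric {0,1} matrix with zero diagonal;
    ``features`` has one row per node.
    """

    adjacency: np.ndarray
    features: np.ndarray
    label: int | None = None
    graph_id: object = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        self.features = np.asarray(self.features, dtype=float)
        validate_adjacency(self.adjacency)
        if self.features.ndim != 2 or self.features.shape[0] != self.adjacency.shape[0]:
            raise ValueError(
                f"features must be N x d with N={self.adjacency.shape[0]}, "
                f"got shape {self.features.shape}"
            )
        if self.features.shape[1] < 1:
            raise ValueError("feature dimension must be >= 1")

    @property
    def node_count(self) -> int:
        return self.adjacency.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency, dtype=float).sum(axis=1)


def validate_adjacency(a: np.ndarray) -> None:
    """Raise ValueError unless ``a`` is square, symmetric, {0,1}, zero-diagonal."""
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency entries must be 0 or 1")


@dataclass
class GraphDataset:
    """An ordered collection of graphs sharing a feature space and label space."""

    graphs: list[Graph] = field(default_factory=list)
    class_count: int = 0
    feature_dim: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        for g in self.graphs:
            if g.feature_dim != self.feature_dim:
                raise ValueError(
                    f"graph {g.graph_id} has feature_dim {g.feature_dim}, "
                    f"dataset expects {self.feature_dim}"
                )
            if g.label is None or not (0 <= g.label < self.class_count):
                raise ValueError(
                    f"graph {g.graph_id} label {g.label} outside "
                    f"[0, {self.class_count})"
                )

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    def __getitem__(self, idx: int) -> Graph:
        return self.graphs[idx]

    @property
    def labels(self) -> np.ndarray:
        return np.array([g.label for g in self.graphs], dtype=int)


def one_hot_features(node_labels: Sequence[int], alphabet_size: int) -> np.ndarray:
    """Encode integer node labels as an N x alphabet_size one-hot matrix."""
    labels = np.asarray(list(node_labels), dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= alphabet_size):
        raise ValueError(
            f"node labels must lie in [0, {alphabet_size}), "
            f"got range [{labels.min()}, {labels.max()}]"
        )
    out = np.zeros((len(labels), alphabet_size), dtype=float)
    if labels.size:
        out[np.arange(len(labels)), labels] = 1.0
    return out


def _require(path: Path) -> Path:
    if not path.is_file():
        raise TUFormatError(f"missing mandatory dataset file: {path}")
    return path


def _read_int_column(path: Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                values.append(int(float(line.split(",")[0])))
    return np.asarray(values, dtype=int)


def read_tu_dataset(directory: str | Path, name: str) -> GraphDataset:
    """Load a TU-format dataset from ``directory`` with file prefix ``name``.

    Node labels (if present) are one-hot encoded; real node attributes (if
    present) are appended after the one-hot block.  With neither file the
    features fall back to an N x 1 all-ones matrix.  Duplicate edges and
    self-loops are dropped with a warning; class labels are remapped to
    contiguous 0-based indices.
    """
    directory = Path(directory)
    edge_path = _require(directory / f"{name}_A.txt")
    indicator_path = _require(directory / f"{name}_graph_indicator.txt")
    labels_path = _require(directory / f"{name}_graph_labels.txt")

    indicator = _read_int_column(indicator_path)  # 1-based graph id per node
    n_nodes = len(indicator)
    raw_labels = _read_int_column(labels_path)
    n_graphs = len(raw_labels)
    if indicator.size and (indicator.min() < 1 or indicator.max() > n_graphs):
        raise TUFormatError(
            f"graph indicator values outside [1, {n_graphs}] in {indicator_path}"
        )

    # contiguous 0-based class indices in sorted label order
    classes = np.unique(raw_labels)
    label_map = {c: i for i, c in enumerate(classes)}
    labels = np.array([label_map[c] for c in raw_labels], dtype=int)

    # global node id -> (graph index, local node id), preserving file order
    graph_of = indicator - 1
    local_id = np.zeros(n_nodes, dtype=int)
    sizes = np.zeros(n_graphs, dtype=int)
    for i, g in enumerate(graph_of):
        local_id[i] = sizes[g]
        sizes[g] += 1
    if np.any(sizes == 0):
        raise TUFormatError("graph indicator leaves some graphs without nodes")

    adjacencies = [np.zeros((s, s), dtype=np.int8) for s in sizes]
    seen_directed: set[tuple[int, int]] = set()
    dropped_loops = dropped_dupes = 0
    with open(edge_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                u_s, v_s = line.replace(",", " ").split()
                u, v = int(u_s) - 1, int(v_s) - 1
            except ValueError as exc:
                raise TUFormatError(
                    f"{edge_path}:{lineno}: cannot parse edge line {line!r}"
                ) from exc
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise GraphIntegrityError(
                    f"{edge_path}:{lineno}: node id out of range in edge ({u + 1}, {v + 1})"
                )
            if graph_of[u] != graph_of[v]:
                raise GraphIntegrityError(
                    f"{edge_path}:{lineno}: edge ({u + 1}, {v + 1}) spans graphs "
                    f"{graph_of[u] + 1} and {graph_of[v] + 1}"
                )
            if u == v:
                dropped_loops += 1
                continue
            a = adjacencies[graph_of[u]]
            lu, lv = local_id[u], local_id[v]
            # both directions of an undirected edge are conventional, not dupes
            if (u, v) in seen_directed:
                dropped_dupes += 1
            seen_directed.add((u, v))
            a[lu, lv] = a[lv, lu] = 1
    if dropped_loops:
        logger.warning("%s: dropped %d self-loop(s)", name, dropped_loops)
    if dropped_dupes:
        logger.warning("%s: collapsed %d duplicate edge(s)", name, dropped_dupes)

    features = _load_node_features(directory, name, indicator, sizes)

    graphs = [
        Graph(adjacency=adjacencies[g], features=features[g], label=int(labels[g]),
              graph_id=g)
        for g in range(n_graphs)
    ]
    dataset = GraphDataset(
        graphs=graphs,
        class_count=len(classes),
        feature_dim=graphs[0].feature_dim,
        name=name,
    )
    logger.info(
        "loaded %s: %d graphs, %d classes, feature_dim %d",
        name, len(dataset), dataset.class_count, dataset.feature_dim,
    )
    return dataset


def _load_node_features(
    directory: Path, name: str, indicator: np.ndarray, sizes: np.ndarray
) -> list[np.ndarray]:
    """Per-graph feature matrices: one-hot labels ++ real attributes, or ones."""
    n_nodes = len(indicator)
    blocks: list[np.ndarray] = []

    label_path = directory / f"{name}_node_labels.txt"
    if label_path.is_file():
        node_labels = _read_int_column(label_path)
        if len(node_labels) != n_nodes:
            raise TUFormatError(
                f"{label_path}: {len(node_labels)} labels for {n_nodes} nodes"
            )
        alphabet = np.unique(node_labels)
        remap = {c: i for i, c in enumerate(alphabet)}
        blocks.append(
            one_hot_features([remap[c] for c in node_labels], len(alphabet))
        )

    attr_path = directory / f"{name}_node_attributes.txt"
    if attr_path.is_file():
        attrs = np.loadtxt(attr_path, delimiter=",", ndmin=2, dtype=float)
        if attrs.shape[0] != n_nodes:
            raise TUFormatError(
                f"{attr_path}: {attrs.shape[0]} rows for {n_nodes} nodes"
            )
        blocks.append(attrs)

    if not blocks:
        blocks.append(np.ones((n_nodes, 1), dtype=float))

    all_features = np.hstack(blocks)
    out, offset = [], 0
    for s in sizes:
        out.append(all_features[offset : offset + s])
        offset += s
    return out


def write_tu_dataset(dataset: GraphDataset, directory: str | Path, name: str) -> None:
    """Write ``dataset`` in TU flat-file format (inverse of :func:`read_tu_dataset`).

    Features are emitted as ``_node_attributes.txt`` so arbitrary real feature
    matrices round-trip.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    offset = 0
    edges, indicator, labels, attr_rows = [], [], [], []
    for g_idx, g in enumerate(dataset.graphs, start=1):
        a = np.asarray(g.adjacency)
        for u, v in zip(*np.nonzero(np.triu(a))):
            edges.append((offset + u + 1, offset + v + 1))
            edges.append((offset + v + 1, offset + u + 1))
        indicator.extend([g_idx] * g.node_count)
        labels.append(g.label)
        attr_rows.extend(", ".join(f"{x:.10g}" for x in row) for row in g.features)
        offset += g.node_count
    (directory / f"{name}_A.txt").write_text(
        "".join(f"{u}, {v}\n" for u, v in edges)
    )
    (directory / f"{name}_graph_indicator.txt").write_text(
        "".join(f"{i}\n" for i in indicator)
    )
    (directory / f"{name}_graph_labels.txt").write_text(
        "".join(f"{y}\n" for y in labels)
    )
    (directory / f"{name}_node_attributes.txt").write_text(
        "".join(f"{row}\n" for row in attr_rows)
    )
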