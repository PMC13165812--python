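"""Ego-network sampling and vectorization into the sampling matrix.

Each node contributes one ego-network: itself plus up to ``ego_size - 1`` of
its highest-degree neighbors (degree measured in the full graph, ties broken
by ascending node id).  The induced local adjacency, zero-padded to
``ego_size x ego_size``, is flattened row-major into one column of the
sampling matrix ``Y``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph_io import Graph

__all__ = [
    "PoolingConfig",
    "EgoNetwork",
    "SamplingMatrix",
    "sample_ego_network",
    "sample_all_egos",
    "vectorize_ego",
    "devectorize_ego",
    "build_sampling_matrix",
]


@dataclass(frozen=True)
class PoolingConfig:
    """Knobs for one pooling level.

    ego_size
        Number of nodes per ego-network (center included).
    confidence_threshold
        Association confidence needed for a row of Y to join a candidate atom.
    coverage_weight
        Reward per newly covered 1-entry relative to the unit penalty per
        overwritten 0-entry in the greedy coverage objective.
    max_atoms
        Hard cap on the dictionary size.
    error_tolerance
        Stop factorizing once this many 1-entries remain uncovered.
    pooling_ratio
        Upper bound on coarsened size as a fraction of the input size.
    binarize_threshold
        Weighted-adjacency entries strictly above this become edges before
        ego sampling on coarsened graphs.
    """

    ego_size: int = 5
    confidence_threshold: float = 0.6
    coverage_weight: float = 1.0
    max_atoms: int = 64
    error_tolerance: float = 0.0
    pooling_ratio: float = 0.5
    binarize_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.ego_size < 2:
            raise ValueError("ego_size must be >= 2")
        if not (0.0 < self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must be in (0, 1]")
        if self.coverage_weight <= 0:
            raise ValueError("coverage_weight must be > 0")
        if self.max_atoms < 1:
            raise ValueError("max_atoms must be >= 1")
        if self.error_tolerance < 0:
            raise ValueError("error_tolerance must be >= 0")
        if not (0.0 < self.pooling_ratio <= 1.0):
            raise ValueError("pooling_ratio must be in (0, 1]")
        if self.binarize_threshold < 0:
            raise ValueError("binarize_threshold must be >= 0")

    def atom_budget(self, n_nodes: int) -> int:
        """Dictionary cap for a graph of ``n_nodes``: ratio bound ∧ max_atoms."""
        return max(1, min(self.max_atoms, math.ceil(self.pooling_ratio * n_nodes)))


@dataclass(frozen=True)
class EgoNetwork:
    """A degree-capped 1-hop neighborhood, center first."""

    center: int
    members: tuple[int, ...]
    local_adjacency: np.ndarray  # ego_size x ego_size, zero-padded
    ego_size: int

    def __post_init__(self) -> None:
        if not self.members or self.members[0] != self.center:
            raise ValueError("members must start with the center node")
        if len(set(self.members)) != len(self.members):
            raise ValueError("members must be distinct")
        a = self.local_adjacency
        if a.shape != (self.ego_size, self.ego_size):
            raise ValueError("local_adjacency must be ego_size x ego_size")


@dataclass(frozen=True)
class SamplingMatrix:
    """Binary (ego_size^2) x N matrix; column t encodes node t's ego-network."""

    matrix: np.ndarray
    column_centers: tuple[int, ...]
    ego_size: int

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def sample_ego_network(graph: Graph, center: int, ego_size: int) -> EgoNetwork:
    """Induced subgraph on ``center`` plus its highest-degree neighbors."""
    n = graph.node_count
    if not (0 <= center < n):
        raise ValueError(f"center {center} not a node of a {n}-node graph")
    a = np.asarray(graph.adjacency)
    degrees = a.sum(axis=1)
    neighbors = np.flatnonzero(a[center])
    # global degree descending, node id ascending
    order = sorted(neighbors, key=lambda v: (-degrees[v], v))
    members = (center, *order[: ego_size - 1])
    local = np.zeros((ego_size, ego_size), dtype=np.uint8)
    idx = np.asarray(members)
    local[: len(members), : len(members)] = a[np.ix_(idx, idx)]
    return EgoNetwork(center=center, members=members, local_adjacency=local,
                      ego_size=ego_size)


def sample_all_egos(graph: Graph, ego_size: int) -> list[EgoNetwork]:
    return [sample_ego_network(graph, t, ego_size) for t in range(graph.node_count)]


def vectorize_ego(ego: EgoNetwork) -> np.ndarray:
    """Row-major flattening of the padded local adjacency (length ego_size^2)."""
    return ego.local_adjacency.reshape(-1).astype(np.uint8)


def devectorize_ego(column: np.ndarray, ego_size: int) -> np.ndarray:
    """Inverse of :func:`vectorize_ego` on a length ego_size^2 vector."""
    column = np.asarray(column)
    if column.size != ego_size * ego_size:
        raise ValueError(f"expected length {ego_size**2}, got {column.size}")
    return column.reshape(ego_size, ego_size)


def build_sampling_matrix(
    graph: Graph, ego_size: int, egos: list[EgoNetwork] | None = None
) -> SamplingMatrix:
    """Stack one vectorized ego-network per node into Y (one column per node)."""
    if egos is None:
        egos = sample_all_egos(graph, ego_size)
    if len(egos) != graph.node_count:
        raise ValueError("need exactly one ego-network per node")
    cols = [vectorize_ego(e) for e in egos]
    matrix = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((ego_size * ego_size, 0), dtype=np.uint8)
    )
    return SamplingMatrix(
        matrix=matrix,
        column_centers=tuple(e.center for e in egos),
        ego_size=ego_size,
    )
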