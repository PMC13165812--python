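"""From sparse codes to a column-stochastic assignment matrix and coarsening.

The affiliation matrix M (N x T) records which nodes sit in which
ego-network; C M^T counts, for each (atom, node) pair, in how many
ego-networks they co-occur.  Dividing column j by the number of ego-networks
containing node j gives the raw assignment weight; an explicit per-column
renormalization then enforces column-stochasticity even when an ego-network
activates several atoms.  Coarsening is the usual X' = S X, A' = S A S^T.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .bmf import AtomDictionary, FactorizationResult, SparseCode, factorize
from .ego import (
    EgoNetwork,
    PoolingConfig,
    build_sampling_matrix,
    sample_all_egos,
)
from .graph_io import Graph

logger = logging.getLogger(__name__)

__all__ = [
    "AffiliationMatrix",
    "AssignmentMatrix",
    "CoarsenedGraph",
    "PoolResult",
    "NoAtomsError",
    "build_affiliation_matrix",
    "cooccurrence_counts",
    "build_assignment_matrix",
    "coarsen",
    "binarize_adjacency",
    "pool_layer",
]


class NoAtomsError(Exception):
    """Factorization produced an empty dictionary; caller should fall back."""


@dataclass(frozen=True)
class AffiliationMatrix:
    """Binary N x T node/ego-network membership matrix with unit diagonal."""

    matrix: np.ndarray

    def ego_counts(self) -> np.ndarray:
        """Number of ego-networks containing each node (>= 1 by construction)."""
        return self.matrix.sum(axis=1).astype(np.int64)


@dataclass(frozen=True)
class AssignmentMatrix:
    """Nonnegative k x N matrix with unit column sums (node -> atom weights)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if np.any(m < 0):
            raise ValueError("assignment weights must be nonnegative")
        if m.shape[1] and not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("assignment columns must sum to 1")

    @property
    def super_node_count(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class CoarsenedGraph:
    features: np.ndarray  # k x d
    adjacency: np.ndarray  # k x k, nonnegative real, symmetric
    atom_provenance: AtomDictionary | None = None

    @property
    def node_count(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class PoolResult:
    coarsened: CoarsenedGraph
    assignment: AssignmentMatrix
    factorization: FactorizationResult
    affiliation: AffiliationMatrix
    egos: tuple[EgoNetwork, ...]
    identity_fallback: bool = False


def build_affiliation_matrix(egos: list[EgoNetwork], n_nodes: int) -> AffiliationMatrix:
    """M[j, t] = 1 iff node j is a member of the ego-network centered at t."""
    if len(egos) != n_nodes:
        raise ValueError("expected one ego-network per node")
    m = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
    for t, ego in enumerate(egos):
        for j in ego.members:
            if not (0 <= j < n_nodes):
                raise ValueError(f"ego member {j} outside node range [0, {n_nodes})")
            m[j, t] = 1
    return AffiliationMatrix(matrix=m)


def cooccurrence_counts(
    code: SparseCode | np.ndarray, affiliation: AffiliationMatrix | np.ndarray
) -> np.ndarray:
    """Entry (i, j): number of ego-networks containing node j with atom i active."""
    c = code.matrix if isinstance(code, SparseCode) else np.asarray(code)
    m = (
        affiliation.matrix
        if isinstance(affiliation, AffiliationMatrix)
        else np.asarray(affiliation)
    )
    if c.shape[1] != m.shape[1]:
        raise ValueError(f"code has {c.shape[1]} columns, affiliation {m.shape[1]}")
    return c.astype(np.int64) @ m.astype(np.int64).T


def build_assignment_matrix(
    code: SparseCode | np.ndarray, affiliation: AffiliationMatrix | np.ndarray
) -> AssignmentMatrix:
    """Normalized atom/node co-occurrence, renormalized to unit column sums.

    Columns with no atom co-occurrence at all receive the uniform assignment
    1/k so no node is dropped from the coarsened graph.
    """
    if not isinstance(affiliation, AffiliationMatrix):
        affiliation = AffiliationMatrix(matrix=np.asarray(affiliation))
    counts = cooccurrence_counts(code, affiliation)
    k = counts.shape[0]
    if k == 0:
        raise NoAtomsError("empty dictionary: no atoms to assign nodes to")
    ego_counts = affiliation.ego_counts()
    if np.any(ego_counts == 0):
        raise ValueError("every node must belong to at least one ego-network")
    raw = counts.astype(float) / ego_counts[None, :].astype(float)
    col_mass = raw.sum(axis=0)
    out = np.empty_like(raw)
    covered = col_mass > 0
    out[:, covered] = raw[:, covered] / col_mass[None, covered]
    out[:, ~covered] = 1.0 / k
    return AssignmentMatrix(matrix=out)


def raw_assignment_weights(
    code: SparseCode | np.ndarray, affiliation: AffiliationMatrix
) -> np.ndarray:
    """Pre-renormalization weights: co-occurrence counts over |E(v_j)|."""
    counts = cooccurrence_counts(code, affiliation)
    return counts.astype(float) / affiliation.ego_counts()[None, :].astype(float)


def coarsen(
    graph: Graph | tuple[np.ndarray, np.ndarray],
    assignment: AssignmentMatrix | np.ndarray,
    atom_provenance: AtomDictionary | None = None,
) -> CoarsenedGraph:
    """X' = S X and A' = S A S^T for one pooling step."""
    if isinstance(graph, Graph):
        a, x = np.asarray(graph.adjacency, dtype=float), graph.features
    else:
        a, x = (np.asarray(v, dtype=float) for v in graph)
    s = (
        assignment.matrix
        if isinstance(assignment, AssignmentMatrix)
        else np.asarray(assignment, dtype=float)
    )
    if s.shape[1] != a.shape[0]:
        raise ValueError(f"assignment has {s.shape[1]} columns for {a.shape[0]} nodes")
    if x.shape[0] != a.shape[0]:
        raise ValueError("feature rows must match adjacency size")
    features = s @ x
    adjacency = s @ a @ s.T
    asym = np.abs(adjacency - adjacency.T).max(initial=0.0)
    if asym > 1e-8:
        raise ValueError(f"coarsened adjacency asymmetric (max dev {asym:.2e})")
    adjacency = (adjacency + adjacency.T) / 2.0  # kill float round-off drift
    return CoarsenedGraph(
        features=features, adjacency=adjacency, atom_provenance=atom_provenance
    )


def binarize_adjacency(a: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Entries strictly above ``threshold`` become edges; diagonal is zeroed."""
    b = (np.asarray(a, dtype=float) > threshold).astype(np.int8)
    b = np.maximum(b, b.T)
    np.fill_diagonal(b, 0)
    return b


def pool_layer(
    adjacency: np.ndarray,
    features: np.ndarray,
    config: PoolingConfig,
) -> PoolResult:
    """One full pooling step: ego sampling -> factorization -> assignment -> coarsen.

    ``adjacency`` may carry real weights (a previous layer's output); it is
    binarized for ego sampling and factorization, while coarsening uses the
    weights as given.  If no atoms are found the graph passes through
    unchanged under an identity assignment.
    """
    a = np.asarray(adjacency, dtype=float)
    x = np.asarray(features, dtype=float)
    n = a.shape[0]
    is_binary = np.isin(a, (0.0, 1.0)).all() and not np.any(np.diagonal(a))
    a_bin = a.astype(np.int8) if is_binary else binarize_adjacency(a, config.binarize_threshold)

    topo = Graph(adjacency=a_bin, features=np.ones((n, 1)))
    egos = sample_all_egos(topo, config.ego_size)
    sampling = build_sampling_matrix(topo, config.ego_size, egos=egos)
    result = factorize(sampling, config, max_atoms=config.atom_budget(n))
    affiliation = build_affiliation_matrix(egos, n)

    if result.atom_count == 0:
        logger.info("no atoms found on %d-node graph; identity pooling fallback", n)
        identity = AssignmentMatrix(matrix=np.eye(n))
        coarsened = CoarsenedGraph(
            features=x.copy(), adjacency=a.copy(), atom_provenance=result.dictionary
        )
        return PoolResult(
            coarsened=coarsened,
            assignment=identity,
            factorization=result,
            affiliation=affiliation,
            egos=tuple(egos),
            identity_fallback=True,
        )

    assignment = build_assignment_matrix(result.code, affiliation)
    coarsened = coarsen((a, x), assignment, atom_provenance=result.dictionary)
    return PoolResult(
        coarsened=coarsened,
        assignment=assignment,
        factorization=result,
        affiliation=affiliation,
        egos=tuple(egos),
        identity_fallback=False,
    )
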