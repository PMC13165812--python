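"""Greedy Boolean matrix factorization of the sampling matrix.

Y (binary, m x T) is approximated as the Boolean product D ∘ C of a binary
dictionary D (m x k) and a binary sparse code C (k x T).  Candidate dictionary
columns are the rows of the row-association matrix R, where R[i, j] = 1 when
the confidence <y_i, y_j> / <y_i, y_i> reaches the threshold.  Each greedy
step picks the (column, row) pair maximizing

    coverage = weight * (newly covered 1s of Y) - (newly overwritten 0s of Y)

over cells not yet covered by the current factorization, and stops when the
atom budget is exhausted, the uncovered mass drops to the tolerance, or no
candidate has positive coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .ego import PoolingConfig, SamplingMatrix

__all__ = [
    "AssociationMatrix",
    "AtomDictionary",
    "SparseCode",
    "FactorizationResult",
    "ReconstructionError",
    "boolean_product",
    "row_association_matrix",
    "coverage_score",
    "best_usage_row",
    "factorize",
    "reconstruction_error",
    "save_factorization",
    "load_factorization",
]


@dataclass(frozen=True)
class AssociationMatrix:
    matrix: np.ndarray  # binary m x m
    threshold: float


@dataclass(frozen=True)
class AtomDictionary:
    """Binary m x k dictionary; column a reshapes to the a-th atom pattern."""

    matrix: np.ndarray

    @property
    def atom_count(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class SparseCode:
    """Binary k x T code; entry (a, t) marks atom a active in ego-network t."""

    matrix: np.ndarray

    @property
    def atom_count(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FactorizationResult:
    dictionary: AtomDictionary
    code: SparseCode
    residual_l1: int
    coverage_trace: tuple[float, ...]

    @property
    def atom_count(self) -> int:
        return self.dictionary.atom_count


class ReconstructionError(NamedTuple):
    uncovered_ones: int
    overcovered_zeros: int


def _as_matrix(y: SamplingMatrix | np.ndarray) -> np.ndarray:
    m = y.matrix if isinstance(y, SamplingMatrix) else np.asarray(y)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("matrix must be binary")
    return m.astype(np.uint8)


def boolean_product(
    d: AtomDictionary | np.ndarray, c: SparseCode | np.ndarray
) -> np.ndarray:
    """Boolean matrix product: OR over a of (D[i,a] AND C[a,t])."""
    dm = d.matrix if isinstance(d, AtomDictionary) else np.asarray(d)
    cm = c.matrix if isinstance(c, SparseCode) else np.asarray(c)
    if dm.shape[1] != cm.shape[0]:
        raise ValueError(f"inner dimensions disagree: {dm.shape} vs {cm.shape}")
    return (dm.astype(np.int64) @ cm.astype(np.int64) > 0).astype(np.uint8)


def row_association_matrix(
    y: SamplingMatrix | np.ndarray, threshold: float
) -> AssociationMatrix:
    """R[i, j] = 1 iff <y_i, y_j> / <y_i, y_i> >= threshold (all-zero rows stay zero)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    ym = _as_matrix(y).astype(np.int64)
    gram = ym @ ym.T
    norms = np.diagonal(gram)
    r = np.zeros_like(gram, dtype=np.uint8)
    nonzero = norms > 0
    # integer-exact comparison: gram >= threshold * norm
    r[nonzero] = (gram[nonzero] >= threshold * norms[nonzero, None]).astype(np.uint8)
    return AssociationMatrix(matrix=r, threshold=threshold)


def coverage_score(
    y: np.ndarray,
    candidate_column: np.ndarray,
    candidate_row: np.ndarray,
    already_covered: np.ndarray,
    weight: float,
) -> float:
    """Greedy objective of the rank-1 pattern column ⊗ row on uncovered cells."""
    ym = np.asarray(y, dtype=bool)
    pattern = np.outer(
        np.asarray(candidate_column, dtype=bool), np.asarray(candidate_row, dtype=bool)
    )
    if pattern.shape != ym.shape:
        raise ValueError("candidate pattern shape does not match Y")
    new = pattern & ~np.asarray(already_covered, dtype=bool)
    gained = int(np.count_nonzero(new & ym))
    spilled = int(np.count_nonzero(new & ~ym))
    return weight * gained - spilled


def best_usage_row(
    y: np.ndarray,
    candidate_column: np.ndarray,
    already_covered: np.ndarray,
    weight: float,
) -> np.ndarray:
    """Per-column greedy optimum usage row for a fixed candidate column.

    The coverage objective is separable across columns of Y, so including
    column t exactly when its marginal contribution is positive maximizes the
    total coverage over all 2^T rows.
    """
    ym = np.asarray(y, dtype=bool)
    col = np.asarray(candidate_column, dtype=bool)
    if col.shape[0] != ym.shape[0]:
        raise ValueError("candidate column length does not match Y")
    new = col[:, None] & ~np.asarray(already_covered, dtype=bool)
    gains = weight * (new & ym).sum(axis=0) - (new & ~ym).sum(axis=0)
    return (gains > 0).astype(np.uint8)


def factorize(
    y: SamplingMatrix | np.ndarray, config: PoolingConfig, max_atoms: int | None = None
) -> FactorizationResult:
    """Greedy Boolean factorization of Y under ``config``.

    ``max_atoms`` overrides ``config.max_atoms`` (used by pooling layers to
    apply the ratio-derived budget).
    """
    ym = _as_matrix(y)
    m, t = ym.shape
    k_max = config.max_atoms if max_atoms is None else max_atoms
    weight = config.coverage_weight

    covered = np.zeros_like(ym, dtype=bool)
    ones = ym.astype(bool)
    residual = int(ones.sum())
    d_cols: list[np.ndarray] = []
    c_rows: list[np.ndarray] = []
    trace: list[float] = []

    if residual > config.error_tolerance and t > 0:
        assoc = row_association_matrix(ym, config.confidence_threshold).matrix
        candidates = [assoc[i].astype(np.uint8) for i in range(m)]
        while len(d_cols) < k_max and residual > config.error_tolerance:
            best_score, best_col, best_row = 0.0, None, None
            for col in candidates:
                if not col.any():
                    continue
                if any(np.array_equal(col, prev) for prev in d_cols):
                    continue  # distinct-columns invariant
                row = best_usage_row(ym, col, covered, weight)
                if not row.any():
                    continue
                score = coverage_score(ym, col, row, covered, weight)
                if score > best_score:  # ties keep the lowest candidate index
                    best_score, best_col, best_row = score, col, row
            if best_col is None or best_score <= 0:
                break
            d_cols.append(best_col)
            c_rows.append(best_row)
            trace.append(float(best_score))
            covered |= np.outer(best_col.astype(bool), best_row.astype(bool))
            residual = int(np.count_nonzero(ones & ~covered))

    k = len(d_cols)
    dictionary = AtomDictionary(
        matrix=np.stack(d_cols, axis=1) if k else np.zeros((m, 0), dtype=np.uint8)
    )
    code = SparseCode(
        matrix=np.stack(c_rows, axis=0) if k else np.zeros((0, t), dtype=np.uint8)
    )
    return FactorizationResult(
        dictionary=dictionary,
        code=code,
        residual_l1=residual,
        coverage_trace=tuple(trace),
    )


def reconstruction_error(
    y: SamplingMatrix | np.ndarray,
    d: AtomDictionary | np.ndarray,
    c: SparseCode | np.ndarray,
) -> ReconstructionError:
    """(uncovered 1s of Y, overwritten 0s of Y) under the factorization D ∘ C."""
    ym = _as_matrix(y).astype(bool)
    approx = boolean_product(d, c).astype(bool)
    if approx.shape != ym.shape:
        raise ValueError("factorization shape does not match Y")
    return ReconstructionError(
        uncovered_ones=int(np.count_nonzero(ym & ~approx)),
        overcovered_zeros=int(np.count_nonzero(~ym & approx)),
    )


def _format_binary(mat: np.ndarray) -> str:
    return "\n".join("".join(str(int(v)) for v in row) for row in mat)


def save_factorization(
    result: FactorizationResult, path: str | Path, ego_size: int, config: PoolingConfig
) -> None:
    """Plain-text archive: JSON header, then D and C as 0/1 digit blocks."""
    header = {
        "ego_size": ego_size,
        "confidence_threshold": config.confidence_threshold,
        "coverage_weight": config.coverage_weight,
        "atom_count": result.atom_count,
        "residual_l1": result.residual_l1,
        "dictionary_shape": list(result.dictionary.matrix.shape),
        "code_shape": list(result.code.matrix.shape),
    }
    blocks = [
        json.dumps(header),
        "# dictionary",
        _format_binary(result.dictionary.matrix),
        "# code",
        _format_binary(result.code.matrix),
    ]
    Path(path).write_text("\n".join(blocks) + "\n")


def load_factorization(path: str | Path) -> tuple[dict, FactorizationResult]:
    lines = Path(path).read_text().splitlines()
    header = json.loads(lines[0])

    def parse_block(start: int, shape: tuple[int, int]) -> tuple[np.ndarray, int]:
        rows, idx = [], start
        for _ in range(shape[0]):
            rows.append([int(ch) for ch in lines[idx]])
            idx += 1
        mat = (
            np.asarray(rows, dtype=np.uint8)
            if rows
            else np.zeros(shape, dtype=np.uint8)
        )
        return mat.reshape(shape), idx

    d_shape = tuple(header["dictionary_shape"])
    c_shape = tuple(header["code_shape"])
    idx = lines.index("# dictionary") + 1
    d_mat, idx = parse_block(idx, d_shape)
    idx = lines.index("# code") + 1
    c_mat, _ = parse_block(idx, c_shape)
    result = FactorizationResult(
        dictionary=AtomDictionary(matrix=d_mat),
        code=SparseCode(matrix=c_mat),
        residual_l1=int(header["residual_l1"]),
        coverage_trace=(),
    )
    return header, result
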