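"""Analytic-hierarchy-process weighting with consistency diagnostics.

Priority weights for the children of each hierarchy node are derived
from positive reciprocal pairwise-comparison matrices on the Saaty 1-9
scale.  The primary extraction method is the principal right
eigenvector (power iteration); the row-geometric-mean is available as
an alternative.  Consistency is judged by

    CI = (lambda_max - n) / (n - 1),     CR = CI / RI(n),

with Saaty's classic random-index table; a matrix is acceptably
consistent when CR < 0.10.  Expert panels are aggregated by
element-wise geometric mean, which preserves reciprocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .errors import (
    InvalidInputError,
    NumericalFailureError,
    UnsupportedOrderError,
)

__all__ = [
    "SAATY_VALUES",
    "RANDOM_INDEX",
    "PairwiseMatrix",
    "MatrixValidationReport",
    "ConsistencyReport",
    "validate_matrix",
    "aggregate_matrices",
    "principal_weights",
    "geometric_mean_weights",
    "consistency_ratio",
    "AHPWeighter",
]

#: admissible single-judgment intensities: 1..9 and their reciprocals
SAATY_VALUES = tuple(sorted({float(k) for k in range(1, 10)} |
                            {1.0 / k for k in range(2, 10)}))

#: Saaty's classic random consistency index by matrix order
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
                6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

_RECIP_TOL = 1e-9


@dataclass(frozen=True)
class PairwiseMatrix:
    """A positive reciprocal comparison matrix at one hierarchy node.

    ``entries[i, j]`` is how strongly child ``labels[i]`` is preferred
    over child ``labels[j]`` on the Saaty scale.
    """

    node_id: str
    entries: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise InvalidInputError("entries must be a square grid")
        if arr.shape[0] < 2:
            raise InvalidInputError("comparison matrix needs n >= 2")
        if not np.all(arr > 0):
            raise InvalidInputError("all entries must be strictly positive")
        object.__setattr__(self, "entries", arr)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) != arr.shape[0]:
            raise InvalidInputError("labels length must match matrix order")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidInputError("labels must be unique")

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class MatrixValidationReport:
    node_id: str
    diagonal_violations: tuple[tuple[int, float], ...]
    reciprocity_violations: tuple[tuple[int, int], ...]
    scale_violations: tuple[tuple[int, int, float], ...]

    @property
    def valid(self) -> bool:
        return not (self.diagonal_violations or self.reciprocity_violations
                    or self.scale_violations)


@dataclass(frozen=True)
class ConsistencyReport:
    lambda_max: float
    n: int
    ci: float
    ri: float
    cr: float

    @property
    def acceptable(self) -> bool:
        """Saaty's rule: consistent enough when CR < 0.10 (equality fails)."""
        return self.cr < 0.10


def _is_saaty(value: float, tol: float = 1e-6) -> bool:
    return any(abs(value - s) <= tol * max(1.0, s) for s in SAATY_VALUES)


def validate_matrix(m: PairwiseMatrix, strict_scale: bool = False,
                    strict: bool = False) -> MatrixValidationReport:
    """Check diagonal, reciprocity and (optionally) Saaty-scale membership.

    With ``strict=True`` any violation raises; otherwise the report
    lists them.  ``strict_scale`` additionally requires every
    above-diagonal entry to be one of 1..9 or a reciprocal thereof
    (disable for aggregated matrices, whose geometric means fall
    between scale points).
    """
    a = m.entries
    n = m.n
    diag = tuple((i, float(a[i, i])) for i in range(n) if abs(a[i, i] - 1.0) > _RECIP_TOL)
    recip = tuple(
        (i, j) for i in range(n) for j in range(i + 1, n)
        if abs(a[j, i] - 1.0 / a[i, j]) > _RECIP_TOL * max(1.0, 1.0 / a[i, j])
    )
    scale: tuple = ()
    if strict_scale:
        scale = tuple((i, j, float(a[i, j]))
                      for i in range(n) for j in range(i + 1, n)
                      if not _is_saaty(a[i, j]))
    report = MatrixValidationReport(node_id=m.node_id, diagonal_violations=diag,
                                    reciprocity_violations=recip,
                                    scale_violations=scale)
    if strict and not report.valid:
        raise InvalidInputError(f"invalid comparison matrix at {m.node_id}: {report}")
    return report


def aggregate_matrices(matrices: Sequence[PairwiseMatrix]) -> PairwiseMatrix:
    """Element-wise geometric mean over an expert panel.

    All matrices must describe the same node with the same child
    ordering.  The geometric mean of reciprocal matrices is reciprocal
    by construction; strict-scale validation does not apply to the
    aggregate.
    """
    if not matrices:
        raise InvalidInputError("no matrices to aggregate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.node_id != first.node_id or m.labels != first.labels:
            raise InvalidInputError("matrices disagree on node_id or labels")
        if m.n != first.n:
            raise InvalidInputError("matrices disagree on order")
    stack = np.stack([m.entries for m in matrices])
    agg = np.exp(np.log(stack).mean(axis=0))
    return PairwiseMatrix(node_id=first.node_id, entries=agg, labels=first.labels)


def principal_weights(m: PairwiseMatrix, tol: float = 1e-10,
                      max_iter: int = 10_000) -> tuple[np.ndarray, ConsistencyReport]:
    """Priority weights as the normalised principal right eigenvector.

    Power iteration on the positive matrix (Perron-Frobenius guarantees
    a unique positive dominant eigenpair).  Returns the weight vector
    (sum 1, all positive) and the consistency report built from the
    principal eigenvalue.
    """
    a = m.entries
    w = np.full(m.n, 1.0 / m.n)
    lam = float(m.n)
    for _ in range(max_iter):
        aw = a @ w
        lam = float(aw.sum())          # since w sums to 1, Aw ~ lambda * w
        w_new = aw / lam
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    else:
        raise NumericalFailureError(
            f"power iteration did not converge in {max_iter} iterations")
    lam = float((a @ w).sum())
    report = consistency_ratio(lam, m.n)
    return w, report


def geometric_mean_weights(m: PairwiseMatrix) -> np.ndarray:
    """Row-geometric-mean priority weights (alternative extraction mode)."""
    g = np.exp(np.log(m.entries).mean(axis=1))
    return g / g.sum()


def consistency_ratio(lambda_max: float, n: int,
                      ri_table: dict[int, float] | None = None) -> ConsistencyReport:
    """Consistency index and ratio for a principal eigenvalue.

    ``n <= 2`` short-circuits to CR = 0 (a 2x2 reciprocal matrix is
    always consistent).  Orders above the RI table raise.
    """
    ri_table = RANDOM_INDEX if ri_table is None else ri_table
    if n < 2:
        raise InvalidInputError("consistency needs n >= 2")
    if n not in ri_table:
        raise UnsupportedOrderError(f"no random index tabulated for n = {n}")
    if lambda_max < n - 1e-9:
        raise InvalidInputError("lambda_max below n is impossible for a "
                                "valid reciprocal positive matrix")
    lambda_max = max(float(lambda_max), float(n))
    ci = (lambda_max - n) / (n - 1)
    ri = ri_table[n]
    cr = 0.0 if n <= 2 else ci / ri
    return ConsistencyReport(lambda_max=lambda_max, n=n, ci=ci, ri=ri, cr=cr)


class AHPWeighter(BaseEstimator):
    """Derive node weights from one or more expert comparison matrices.

    ``fit`` accepts a single :class:`PairwiseMatrix`, a raw square
    array, or a sequence of matrices from an expert panel (aggregated by
    element-wise geometric mean before extraction).

    Parameters
    ----------
    method : {"eigen", "geomean"}
        Principal-eigenvector (default) or row-geometric-mean weights.
    tol, max_iter :
        Power-iteration convergence control (eigen method).
    strict_scale : bool
        Validate individual expert entries against the Saaty scale.

    Attributes
    ----------
    weights_ : ndarray
        Positive weights summing to 1, ordered as ``labels_``.
    lambda_max_ : float
    consistency_ : ConsistencyReport
    aggregate_ : PairwiseMatrix
        The matrix weights were extracted from.
    """

    def __init__(self, method: Literal["eigen", "geomean"] = "eigen",
                 tol: float = 1e-10, max_iter: int = 10_000,
                 strict_scale: bool = False):
        self.method = method
        self.tol = tol
        self.max_iter = max_iter
        self.strict_scale = strict_scale

    def _coerce(self, X) -> list[PairwiseMatrix]:
        if isinstance(X, PairwiseMatrix):
            return [X]
        if isinstance(X, np.ndarray) or (
                isinstance(X, (list, tuple)) and X
                and not isinstance(X[0], PairwiseMatrix)):
            arr = np.asarray(X, dtype=float)
            labels = tuple(f"c{i+1}" for i in range(arr.shape[0]))
            return [PairwiseMatrix(node_id="node", entries=arr, labels=labels)]
        return list(X)

    def fit(self, X, y=None):
        matrices = self._coerce(X)
        for m in matrices:
            validate_matrix(m, strict_scale=self.strict_scale, strict=True)
        agg = matrices[0] if len(matrices) == 1 else aggregate_matrices(matrices)
        if self.method == "eigen":
            weights, report = principal_weights(agg, tol=self.tol,
                                                max_iter=self.max_iter)
        elif self.method == "geomean":
            weights = geometric_mean_weights(agg)
            # lambda_max still diagnosed from the aggregate for CR reporting
            _, report = principal_weights(agg, tol=self.tol, max_iter=self.max_iter)
        else:
            raise InvalidInputError(f"unknown method {self.method!r}")
        self.aggregate_ = agg
        self.labels_ = list(agg.labels)
        self.weights_ = weights
        self.lambda_max_ = report.lambda_max
        self.consistency_ = report
        return self

    def weight_series(self):
        import pandas as pd
        return pd.Series(self.weights_, index=self.labels_, name=self.aggregate_.node_id)
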