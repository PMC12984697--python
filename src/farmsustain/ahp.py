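"""Analytic hierarchy process: expert judgment aggregation, priority
weights, consistency checking, and the weighted composite index.

Experts compare criteria pairwise on Saaty's 1-9 scale; judgments are
aggregated entrywise by the geometric mean (which preserves reciprocity),
and priority weights are read off either by the row-average approximation
(normalise each column to sum 1, then average rows) or by the principal
right eigenvector.  Consistency is summarised by

    lambda_max = mean_i (A w)_i / w_i,
    CI = (lambda_max - n) / (n - 1),
    CR = CI / RI(n),

with CR < 0.10 the conventional acceptability bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PairwiseMatrix",
    "AHPResult",
    "RANDOM_INDEX",
    "aggregate_judgments",
    "priority_weights",
    "consistency",
    "composite_index",
]

#: Saaty's random consistency index by matrix order.
RANDOM_INDEX = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}

_RECIPROCITY_TOL = 1e-9


@dataclass(frozen=True)
class PairwiseMatrix:
    """Positive reciprocal pairwise-comparison matrix with criterion labels."""

    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] < 2:
            raise ValueError("pairwise matrix must be square with n >= 2")
        if not (a > 0).all():
            raise ValueError("pairwise matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=_RECIPROCITY_TOL):
            raise ValueError("pairwise matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-6):
            raise ValueError("pairwise matrix must be reciprocal (a_ij * a_ji = 1)")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"c{i + 1}" for i in range(a.shape[0]))
            )
        elif len(self.labels) != a.shape[0]:
            raise ValueError("label count does not match matrix order")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AHPResult:
    weights: np.ndarray
    lambda_max: float
    ci: float
    cr: float
    ri: float
    labels: tuple[str, ...] = field(default_factory=tuple)


def aggregate_judgments(matrices: Sequence[PairwiseMatrix]) -> PairwiseMatrix:
    """Entrywise geometric mean of expert matrices.

    The geometric mean of reciprocal matrices is reciprocal; the lower
    triangle is rebuilt from the upper one so the property holds exactly
    in floating point.
    """
    if not matrices:
        raise ValueError("at least one expert matrix is required")
    n = matrices[0].n
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.n != n or m.labels != labels:
            raise ValueError("expert matrices must share dimension and labels")
    logs = np.mean([np.log(m.values) for m in matrices], axis=0)
    agg = np.exp(logs)
    out = np.ones_like(agg)
    iu = np.triu_indices(n, k=1)
    out[iu] = agg[iu]
    out[(iu[1], iu[0])] = 1.0 / agg[iu]
    return PairwiseMatrix(out, labels)


def priority_weights(matrix: PairwiseMatrix, method: str = "row_average") -> np.ndarray:
    """Priority weight vector, normalised to sum 1.

    ``row_average`` is the column-normalised row-mean approximation;
    ``eigenvector`` is the principal right eigenvector by power iteration.
    """
    a = matrix.values
    if method == "row_average":
        w = (a / a.sum(axis=0, keepdims=True)).mean(axis=1)
        return w / w.sum()
    if method == "eigenvector":
        w = np.full(matrix.n, 1.0 / matrix.n)
        for _ in range(10_000):
            w_new = a @ w
            w_new /= w_new.sum()
            if np.max(np.abs(w_new - w)) < 1e-12:
                return w_new
            w = w_new
        raise RuntimeError("power iteration did not converge")
    raise ValueError(f"unknown weight method {method!r}")


def consistency(
    matrix: PairwiseMatrix,
    weights: np.ndarray | None = None,
    ri: float | None = None,
    method: str = "row_average",
) -> AHPResult:
    """Consistency diagnostics (lambda_max, CI, CR) for a pairwise matrix.

    ``weights`` defaults to :func:`priority_weights` with ``method``.
    ``ri`` defaults to Saaty's tabulated random index for the matrix order.
    """
    if weights is None:
        weights = priority_weights(matrix, method=method)
    w = np.asarray(weights, dtype=float)
    if w.shape != (matrix.n,) or (w <= 0).any():
        raise ValueError("weights must be positive and match the matrix order")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    if ri is None:
        if matrix.n not in RANDOM_INDEX:
            raise ValueError(
                f"no tabulated random index for n={matrix.n}; pass ri explicitly"
            )
        ri = RANDOM_INDEX[matrix.n]
    lambda_max = float(np.mean((matrix.values @ w) / w))
    ci = (lambda_max - matrix.n) / (matrix.n - 1)
    cr = ci / ri if ri > 0 else 0.0
    return AHPResult(
        weights=w, lambda_max=lambda_max, ci=ci, cr=cr, ri=ri, labels=matrix.labels
    )


def composite_index(
    esi: np.ndarray | Iterable[float],
    ensi: np.ndarray | Iterable[float],
    ssi: np.ndarray | Iterable[float],
    weights: Sequence[float],
) -> np.ndarray:
    """Composite sustainability index: CSI = w1*ESI + w2*EnSI + w3*SSI.

    ``weights`` is ordered (economic, environmental, social) to match the
    weight vector produced from the dimension comparison matrix.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("exactly three dimension weights are required")
    if (w <= 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must be positive and sum to 1")
    scores = [np.asarray(s, dtype=float) for s in (esi, ensi, ssi)]
    if len({s.shape for s in scores}) != 1:
        raise ValueError("dimension score vectors must have identical shape")
    for s in scores:
        if ((s < -1e-12) | (s > 1 + 1e-12)).any():
            raise ValueError("dimension scores must lie in [0, 1]")
    return w[0] * scores[0] + w[1] * scores[1] + w[2] * scores[2]
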