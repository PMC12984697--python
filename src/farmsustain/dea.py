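"""Input-oriented Data Envelopment Analysis (DEA) and efficiency grouping.

Each farm (decision-making unit) is scored against the convex hull of the
observed input-output bundles.  Under the input orientation the radial
technical efficiency of farm *o* is the optimum of the envelopment LP

    min theta
    s.t.  sum_j lambda_j x_ij <= theta * x_io    for each input i
          sum_j lambda_j y_rj >= y_ro            for each output r
          sum_j lambda_j = 1                     (VRS only)
          lambda_j >= 0,

so theta is the largest equiproportionate input contraction feasible at
the farm's current output.  theta = 1 means the farm lies on the frontier.
An optional second stage maximises total slack at fixed theta to identify
residual (non-radial) input excess; scores are defined by stage one alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "DEAProblem",
    "EfficiencyResult",
    "GROUP_LABELS",
    "solve_input_oriented",
    "classify_groups",
    "summarize_scores",
]

GROUP_LABELS = ("inefficient", "moderately_efficient", "efficient")

#: Inputs are floored at this fraction of the column mean: a radial model
#: is ill-posed for a unit with a zero input (it could be contracted for
#: free along that axis), and survey near-zeros are placeholders.
INPUT_FLOOR_FRACTION = 1e-6

_LP_TOL = 1e-8


@dataclass
class DEAProblem:
    """Inputs (farms x m), outputs (farms x s), and frontier assumptions."""

    inputs: np.ndarray
    outputs: np.ndarray
    rts: str = "vrs"  # "vrs" or "crs"

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        y = np.asarray(self.outputs, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if x.shape[0] != y.shape[0]:
            raise ValueError("inputs and outputs must cover the same farms")
        if x.shape[0] < 1:
            raise ValueError("at least one farm is required")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("NaN values are not allowed in a DEA problem")
        if (y <= 0).any():
            raise ValueError("all outputs must be strictly positive")
        if (x < 0).any():
            raise ValueError("inputs must be nonnegative")
        if self.rts not in ("vrs", "crs"):
            raise ValueError("rts must be 'vrs' or 'crs'")
        floor = INPUT_FLOOR_FRACTION * x.mean(axis=0)
        n_floored = int((x < floor).sum())
        if n_floored:
            warnings.warn(
                f"floored {n_floored} near-zero input value(s) at "
                "1e-6 x column mean",
                stacklevel=2,
            )
        self.inputs = np.maximum(x, floor)
        self.outputs = y

    @property
    def n_farms(self) -> int:
        return self.inputs.shape[0]


@dataclass
class EfficiencyResult:
    theta: np.ndarray  # radial score per farm, in (0, 1]
    lambdas: np.ndarray  # farms x farms peer-weight matrix
    peers: list[list[int]]  # indices of reference farms (lambda > tol)
    slacks: np.ndarray | None = None  # farms x (m + s) stage-two slacks
    groups: np.ndarray | None = None
    rts: str = "vrs"
    meta: dict = field(default_factory=dict)


def solve_input_oriented(problem: DEAProblem, slack_stage: bool = False) -> EfficiencyResult:
    """Radial input-oriented efficiency for every farm in the problem.

    Solves one envelopment LP per farm (HiGHS).  With ``slack_stage=True``
    a second LP per farm maximises total slack at the fixed radial score.
    """
    # Radial scores are units-invariant, so rescale columns to unit mean
    # for LP conditioning; peer weights are unaffected.
    x = problem.inputs / problem.inputs.mean(axis=0)
    y = problem.outputs / problem.outputs.mean(axis=0)
    n, m = x.shape
    s = y.shape[1]
    vrs = problem.rts == "vrs"

    theta = np.empty(n)
    lambdas = np.zeros((n, n))
    slacks = np.zeros((n, m + s)) if slack_stage else None

    c = np.zeros(n + 1)
    c[0] = 1.0
    # Constraint blocks shared across farms; only the evaluated farm's
    # column/rhs changes.
    for o in range(n):
        a_ub = np.zeros((m + s, n + 1))
        a_ub[:m, 0] = -x[o]
        a_ub[:m, 1:] = x.T
        a_ub[m:, 1:] = -y.T
        b_ub = np.concatenate([np.zeros(m), -y[o]])
        a_eq = np.zeros((1, n + 1)) if vrs else None
        if vrs:
            a_eq[0, 1:] = 1.0
        res = linprog(
            c,
            A_ub=a_ub,
            b_ub=b_ub,
            A_eq=a_eq,
            b_eq=[1.0] if vrs else None,
            bounds=[(0, None)] * (n + 1),
            method="highs",
            options={"primal_feasibility_tolerance": _LP_TOL},
        )
        if not res.success:
            raise RuntimeError(f"envelopment LP failed for farm {o}: {res.message}")
        theta[o] = min(res.x[0], 1.0)
        lambdas[o] = res.x[1:]
        if slack_stage:
            slacks[o] = _max_slacks(x, y, o, theta[o], vrs)

    peers = [list(np.flatnonzero(lambdas[o] > 1e-6)) for o in range(n)]
    return EfficiencyResult(
        theta=theta,
        lambdas=lambdas,
        peers=peers,
        slacks=slacks,
        rts=problem.rts,
        meta={"n_farms": n, "n_inputs": m, "n_outputs": s},
    )


def _max_slacks(x: np.ndarray, y: np.ndarray, o: int, theta: float, vrs: bool) -> np.ndarray:
    """Stage two: maximise total input + output slack at fixed theta."""
    n, m = x.shape
    s = y.shape[1]
    nv = n + m + s  # lambdas, input slacks, output slacks
    c = np.zeros(nv)
    c[n:] = -1.0
    a_eq_rows = []
    b_eq = []
    for i in range(m):
        row = np.zeros(nv)
        row[:n] = x[:, i]
        row[n + i] = 1.0
        a_eq_rows.append(row)
        b_eq.append(theta * x[o, i])
    for r in range(s):
        row = np.zeros(nv)
        row[:n] = y[:, r]
        row[n + m + r] = -1.0
        a_eq_rows.append(row)
        b_eq.append(y[o, r])
    if vrs:
        row = np.zeros(nv)
        row[:n] = 1.0
        a_eq_rows.append(row)
        b_eq.append(1.0)
    res = linprog(
        c,
        A_eq=np.array(a_eq_rows),
        b_eq=b_eq,
        bounds=[(0, None)] * nv,
        method="highs",
    )
    if not res.success:
        return np.full(m + s, np.nan)
    return res.x[n:]


def classify_groups(
    scores: np.ndarray | Sequence[float], thresholds: tuple[float, float] = (0.50, 0.75)
) -> np.ndarray:
    """Label farms by efficiency band.

    The bands are closed/open so the partition of (0, 1] is exhaustive:
    inefficient [0, t1], moderately_efficient (t1, t2), efficient [t2, 1].
    """
    t = np.asarray(scores, dtype=float)
    if ((t <= 0) | (t > 1 + 1e-9)).any():
        raise ValueError("efficiency scores must lie in (0, 1]")
    lo, hi = thresholds
    if not (0 < lo < hi <= 1):
        raise ValueError("thresholds must satisfy 0 < lo < hi <= 1")
    labels = np.where(
        t <= lo, GROUP_LABELS[0], np.where(t < hi, GROUP_LABELS[1], GROUP_LABELS[2])
    )
    return labels


def summarize_scores(
    scores: np.ndarray | Sequence[float], thresholds: tuple[float, float] = (0.50, 0.75)
) -> dict:
    """Mean / min / max / SD of the scores plus frequency counts by band."""
    t = np.asarray(scores, dtype=float)
    if t.size == 0:
        raise ValueError("no scores to summarise")
    labels = classify_groups(t, thresholds)
    counts = {g: int((labels == g).sum()) for g in GROUP_LABELS}
    return {
        "n": int(t.size),
        "mean": float(t.mean()),
        "min": float(t.min()),
        "max": float(t.max()),
        "sd": float(t.std(ddof=1)) if t.size > 1 else 0.0,
        "n_frontier": int((t >= 1 - 1e-9).sum()),
        "band_counts": counts,
    }
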