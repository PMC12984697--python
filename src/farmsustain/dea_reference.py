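"""Exhaustive vertex-enumeration reference solver for the input-oriented
envelopment problem.

This is a deliberately independent cross-check for :mod:`farmsustain.dea`:
instead of calling an LP solver it enumerates every candidate basic
feasible solution of the envelopment polyhedron (all active-set
combinations of the constraints), keeps the feasible ones, and returns the
minimum radial score found.  Complexity is combinatorial, so it is only
usable for small instances (roughly <= 12 farms), which is exactly its
purpose: validating the production solver on small random problems.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["brute_force_theta", "brute_force_scores"]

_FEAS_TOL = 1e-7


def brute_force_theta(
    inputs: np.ndarray, outputs: np.ndarray, o: int, rts: str = "vrs"
) -> float:
    """Radial input-oriented efficiency of farm ``o`` by vertex enumeration.

    Variables are v = (theta, lambda_1..lambda_n).  Constraints:
    inputs   sum_j lambda_j x_ij - theta x_io <= 0
    outputs  y_ro - sum_j lambda_j y_rj       <= 0
    signs    -lambda_j                        <= 0
    VRS      sum_j lambda_j                    = 1   (equality, always active)

    Every vertex of the feasible region activates n+1 independent
    constraints; the optimum of a bounded LP is attained at a vertex.
    """
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(outputs, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, m = x.shape
    s = y.shape[1]
    nvar = n + 1

    # Inequality rows G v <= h.
    rows = []
    rhs = []
    for i in range(m):
        row = np.concatenate([[-x[o, i]], x[:, i]])
        rows.append(row)
        rhs.append(0.0)
    for r in range(s):
        row = np.concatenate([[0.0], -y[:, r]])
        rows.append(row)
        rhs.append(-y[o, r])
    for j in range(n):
        row = np.zeros(nvar)
        row[1 + j] = -1.0
        rows.append(row)
        rhs.append(0.0)
    G = np.array(rows)
    h = np.array(rhs)

    eq_rows = []
    eq_rhs = []
    if rts == "vrs":
        row = np.zeros(nvar)
        row[1:] = 1.0
        eq_rows.append(row)
        eq_rhs.append(1.0)
    elif rts != "crs":
        raise ValueError("rts must be 'vrs' or 'crs'")

    n_active = nvar - len(eq_rows)
    best = np.inf
    for active in combinations(range(G.shape[0]), n_active):
        A = np.vstack([G[list(active)]] + eq_rows) if eq_rows else G[list(active)]
        b = np.concatenate([h[list(active)], eq_rhs]) if eq_rows else h[list(active)]
        try:
            v = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if not np.isfinite(v).all():
            continue
        if (G @ v <= h + _FEAS_TOL).all():
            best = min(best, v[0])
    if not np.isfinite(best):
        raise RuntimeError("no feasible vertex found (malformed problem)")
    return float(best)


def brute_force_scores(inputs: np.ndarray, outputs: np.ndarray, rts: str = "vrs") -> np.ndarray:
    """Vector of brute-force radial scores for every farm."""
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    return np.array([brute_force_theta(x, outputs, o, rts=rts) for o in range(x.shape[0])])
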