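"""Two-limit Tobit regression of bounded efficiency scores on farm
covariates, with average marginal effects and standard diagnostics.

The latent model is y* = x'beta + eps, eps ~ N(0, sigma^2), observed as
y = L when y* <= L, y = U when y* >= U, and y = y* in between (here
L = 0, U = 1 for DEA efficiency scores, where frontier farms pile up at
1).  The log-likelihood is maximised by quasi-Newton on (beta, log sigma)
from an OLS warm start; standard errors come from the observed
information (numerical Hessian at the optimum).

Average marginal effects on the observed (censored) outcome follow the
standard decomposition: dE[y|x]/dx_j = beta_j * P(L < y* < U), so

    AME_j = beta_j * mean_i [Phi((U - x_i'b)/s) - Phi((L - x_i'b)/s)],

i.e. every non-intercept AME is the coefficient shrunk by one common
in-sample probability of being uncensored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr

from .group_comparison import TestResult

__all__ = [
    "TobitFit",
    "fit",
    "average_marginal_effects",
    "lr_test",
    "vif",
    "white_test",
]

_LIMIT_TOL = 1e-9


@dataclass
class TobitFit:
    beta: np.ndarray
    sigma: float
    log_likelihood: float
    n_uncensored: int
    n_left: int
    n_right: int
    covariance: np.ndarray  # for (beta, log sigma)
    se: np.ndarray  # for beta
    z: np.ndarray
    p: np.ndarray
    ames: np.ndarray  # per non-intercept slope; NaN for the intercept slot
    uncensored_share: float  # the common AME/beta scalar
    converged: bool
    lower: float
    upper: float
    names: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.n_uncensored + self.n_left + self.n_right


def _neg_loglik_and_grad(params, y, X, lower, upper, masks):
    """Negative two-limit Tobit log-likelihood and gradient in (beta, log sigma)."""
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    xb = X @ beta
    mid, left, right = masks

    ll = 0.0
    grad_beta = np.zeros_like(beta)
    grad_ls = 0.0

    if mid.any():
        z = (y[mid] - xb[mid]) / sigma
        ll += np.sum(-np.log(sigma) + stats.norm.logpdf(z))
        grad_beta += X[mid].T @ (z / sigma)
        grad_ls += np.sum(z**2 - 1.0)
    if right.any():
        zU = (upper - xb[right]) / sigma
        ll += np.sum(log_ndtr(-zU))
        ratio = np.exp(stats.norm.logpdf(zU) - log_ndtr(-zU))  # phi/(1-Phi)
        grad_beta += X[right].T @ (ratio / sigma)
        grad_ls += np.sum(zU * ratio)
    if left.any():
        zL = (lower - xb[left]) / sigma
        ll += np.sum(log_ndtr(zL))
        ratio = np.exp(stats.norm.logpdf(zL) - log_ndtr(zL))  # phi/Phi
        grad_beta += X[left].T @ (-ratio / sigma)
        grad_ls += np.sum(-zL * ratio)

    return -ll, -np.concatenate([grad_beta, [grad_ls]])


def _numerical_hessian(fun, params, eps=1e-5):
    """Central-difference Hessian of a scalar function via its gradient."""
    k = params.size
    H = np.zeros((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps * max(1.0, abs(params[j]))
        _, g_plus = fun(params + step)
        _, g_minus = fun(params - step)
        H[:, j] = (g_plus - g_minus) / (2 * step[j])
    return (H + H.T) / 2


def fit(
    y: np.ndarray,
    X: np.ndarray,
    lower: float = 0.0,
    upper: float = 1.0,
    names: Sequence[str] | None = None,
) -> TobitFit:
    """Maximum-likelihood two-limit Tobit fit.

    ``X`` must include the intercept column.  Observations within
    ``1e-9`` of a limit are treated as censored at that limit.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X must cover the same observations")
    if lower >= upper:
        raise ValueError("lower limit must be below upper limit")
    if ((y < lower - _LIMIT_TOL) | (y > upper + _LIMIT_TOL)).any():
        raise ValueError("responses must lie within [lower, upper]")
    if n <= p + 1:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _dependent_columns(X)
        labels = [names[j] if names else f"x{j}" for j in bad]
        raise ValueError(f"design matrix is rank deficient; offending columns: {labels}")

    left = np.abs(y - lower) < _LIMIT_TOL
    right = np.abs(y - upper) < _LIMIT_TOL
    mid = ~(left | right)
    if not mid.any():
        raise ValueError("all observations are censored; the model is not identified")
    masks = (mid, left, right)

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sigma0 = max(float(np.sqrt(np.mean(resid**2))), 1e-4)
    x0 = np.concatenate([beta0, [np.log(sigma0)]])

    res = optimize.minimize(
        _neg_loglik_and_grad,
        x0,
        args=(y, X, lower, upper, masks),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    params = res.x
    converged = bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-5
    beta = params[:-1]
    sigma = float(np.exp(params[-1]))
    loglik = -float(res.fun)

    H = _numerical_hessian(
        lambda q: _neg_loglik_and_grad(q, y, X, lower, upper, masks), params
    )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zscores = np.where(se > 0, beta / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(zscores))

    share = float(
        np.mean(
            stats.norm.cdf((upper - X @ beta) / sigma)
            - stats.norm.cdf((lower - X @ beta) / sigma)
        )
    )
    intercept_col = _intercept_column(X)
    ames = beta * share
    if intercept_col is not None:
        ames = ames.copy()
        ames[intercept_col] = np.nan

    return TobitFit(
        beta=beta,
        sigma=sigma,
        log_likelihood=loglik,
        n_uncensored=int(mid.sum()),
        n_left=int(left.sum()),
        n_right=int(right.sum()),
        covariance=cov,
        se=se,
        z=zscores,
        p=pvals,
        ames=ames,
        uncensored_share=share,
        converged=converged,
        lower=lower,
        upper=upper,
        names=tuple(names) if names else tuple(f"x{j}" for j in range(p)),
        meta={"optimizer": "BFGS", "grad_norm": float(np.linalg.norm(res.jac))},
    )


def _intercept_column(X: np.ndarray) -> int | None:
    for j in range(X.shape[1]):
        if np.allclose(X[:, j], 1.0):
            return j
    return None


def _dependent_columns(X: np.ndarray) -> list[int]:
    """Columns not selected by a rank-revealing pivoted QR."""
    from scipy.linalg import qr

    r = np.linalg.matrix_rank(X)
    _, _, piv = qr(X, pivoting=True)
    return sorted(piv[r:].tolist())


def average_marginal_effects(fit_result: TobitFit, X: np.ndarray) -> np.ndarray:
    """Recompute AMEs on the observed outcome for an arbitrary sample ``X``.

    AME_j = beta_j * mean_i [Phi((U - x_i'b)/s) - Phi((L - x_i'b)/s)];
    the intercept slot is NaN.
    """
    if not fit_result.converged:
        raise RuntimeError("fit did not converge; marginal effects unavailable")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    xb = X @ fit_result.beta
    share = float(
        np.mean(
            stats.norm.cdf((fit_result.upper - xb) / fit_result.sigma)
            - stats.norm.cdf((fit_result.lower - xb) / fit_result.sigma)
        )
    )
    ames = fit_result.beta * share
    j = _intercept_column(X)
    if j is not None:
        ames = ames.copy()
        ames[j] = np.nan
    return ames


def discrete_ames(fit_result: TobitFit, X: np.ndarray, column: int) -> float:
    """Discrete-difference AME for a binary covariate: mean E[y|x1]-E[y|x0]."""
    X1 = X.copy()
    X0 = X.copy()
    X1[:, column] = 1.0
    X0[:, column] = 0.0
    return float(np.mean(_censored_expectation(fit_result, X1) - _censored_expectation(fit_result, X0)))


def _censored_expectation(fit_result: TobitFit, X: np.ndarray) -> np.ndarray:
    """E[y|x] under the two-limit model."""
    b, s = fit_result.beta, fit_result.sigma
    L, U = fit_result.lower, fit_result.upper
    xb = X @ b
    zL = (L - xb) / s
    zU = (U - xb) / s
    return (
        L * stats.norm.cdf(zL)
        + U * stats.norm.sf(zU)
        + xb * (stats.norm.cdf(zU) - stats.norm.cdf(zL))
        + s * (stats.norm.pdf(zL) - stats.norm.pdf(zU))
    )


def lr_test(full: TobitFit, null: TobitFit) -> TestResult:
    """Likelihood-ratio test of the full fit against the intercept-only fit."""
    if full.n_obs != null.n_obs:
        raise ValueError("fits must be on the same sample")
    df = len(full.beta) - len(null.beta)
    if df < 0:
        raise ValueError("null model has more parameters than the full model")
    lr = max(2.0 * (full.log_likelihood - null.log_likelihood), 0.0)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return TestResult(statistic=lr, p_value=p, df=df, method="likelihood-ratio")


def vif(X: np.ndarray, names: Sequence[str] | None = None) -> dict[str, float]:
    """Centered variance inflation factors for non-intercept regressors.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the remaining
    regressors plus an intercept; perfect collinearity yields ``inf``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    icol = _intercept_column(X)
    cols = [j for j in range(X.shape[1]) if j != icol]
    if len(cols) < 2:
        raise ValueError("need at least two non-intercept regressors")
    labels = names if names else [f"x{j}" for j in range(X.shape[1])]
    out = {}
    for j in cols:
        others = [k for k in cols if k != j]
        Z = np.column_stack([np.ones(X.shape[0])] + [X[:, k] for k in others])
        yj = X[:, j]
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[labels[j]] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[labels[j]] = np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def white_test(residuals: np.ndarray, X: np.ndarray) -> TestResult:
    """White's general heteroskedasticity test.

    Regresses squared residuals on the regressors, their squares, and
    their pairwise cross products (duplicated/collinear terms dropped by a
    rank check); the statistic is n * R^2 referred to a chi-square with
    df = number of retained auxiliary regressors.
    """
    e = np.asarray(residuals, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if e.shape != (n,):
        raise ValueError("residuals must match the design matrix rows")
    icol = _intercept_column(X)
    cols = [j for j in range(X.shape[1]) if j != icol]
    terms = [np.ones(n)]
    for j in cols:
        terms.append(X[:, j])
    for a_idx, j in enumerate(cols):
        for k in cols[a_idx:]:
            terms.append(X[:, j] * X[:, k])
    Z = np.column_stack(terms)
    # Greedy rank-based pruning keeps the first independent columns.
    keep = [0]
    for j in range(1, Z.shape[1]):
        trial = Z[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    Z = Z[:, keep]
    df = Z.shape[1] - 1
    if df < 1:
        raise ValueError("auxiliary design is degenerate")
    y_aux = e**2
    coef, *_ = np.linalg.lstsq(Z, y_aux, rcond=None)
    resid = y_aux - Z @ coef
    ss_tot = np.sum((y_aux - y_aux.mean()) ** 2)
    if ss_tot <= 1e-12 * n * max(1.0, y_aux.mean() ** 2):  # constant e^2
        r2 = 0.0
    else:
        r2 = min(max(1.0 - np.sum(resid**2) / ss_tot, 0.0), 1.0)
    stat = n * r2
    return TestResult(
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df)),
        df=df,
        method="white",
    )
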