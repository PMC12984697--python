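"""Normality screening and nonparametric comparison of sustainability
scores across efficiency groups.

The omnibus comparison is the Kruskal-Wallis H test with midranks for
ties and the usual tie-correction factor

    H = [12 / (N(N+1))] * sum_i n_i (Rbar_i - (N+1)/2)^2  /  C,
    C = 1 - sum_t (t^3 - t) / (N^3 - N),

referred to a chi-square with k-1 degrees of freedom; for pooled sample
sizes up to a small bound an exact permutation p-value is available by
complete enumeration of group assignments.  Normality within groups is
screened with the Shapiro-Wilk test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "shapiro_wilk",
    "kruskal_wallis",
    "compare_sustainability_by_group",
]

_EXACT_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk W test of normality (Royston's approximation).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = stats.shapiro(x)
    return TestResult(statistic=float(w), p_value=float(p), method="shapiro-wilk")


def _h_statistic(ranks: np.ndarray, sizes: Sequence[int], correction: float) -> float:
    """H from pooled midranks split consecutively into groups of ``sizes``."""
    n = ranks.size
    h = 0.0
    start = 0
    for ni in sizes:
        rbar = ranks[start : start + ni].mean()
        h += ni * (rbar - (n + 1) / 2) ** 2
        start += ni
    return (12.0 / (n * (n + 1))) * h / correction


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "asymptotic"
) -> TestResult:
    """Kruskal-Wallis H test over two or more independent groups.

    ``method='asymptotic'`` uses the chi-square reference with k-1 df;
    ``method='exact'`` enumerates all assignments of the pooled midranks
    to groups (only for pooled N <= 10).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    if correction == 0:
        raise ValueError("all observations are identical; H is undefined")
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    h = _h_statistic(ranks, sizes, correction)
    df = len(arrays) - 1

    if method == "asymptotic":
        p = float(stats.chi2.sf(h, df))
        return TestResult(statistic=h, p_value=p, df=df, method="kruskal-wallis")
    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ValueError(f"exact permutation limited to pooled N <= {_EXACT_MAX_N}")
        count_ge = 0
        total = 0
        for perm_ranks in _group_assignments(ranks, sizes):
            total += 1
            if _h_statistic(perm_ranks, sizes, correction) >= h - 1e-12:
                count_ge += 1
        return TestResult(
            statistic=h,
            p_value=count_ge / total,
            df=df,
            method="kruskal-wallis-exact",
        )
    raise ValueError(f"unknown method {method!r}")


def _group_assignments(ranks: np.ndarray, sizes: Sequence[int]):
    """Yield pooled-rank vectors for every split into groups of ``sizes``."""
    idx = tuple(range(ranks.size))

    def rec(remaining: tuple[int, ...], k: int):
        if k == len(sizes) - 1:
            yield ranks[list(remaining)]
            return
        for chosen in combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in chosen)
            for tail in rec(rest, k + 1):
                yield np.concatenate([ranks[list(chosen)], tail])

    yield from rec(idx, 0)


def compare_sustainability_by_group(
    scores: pd.DataFrame,
    labels: Sequence[str],
    columns: Sequence[str] = ("economic", "social", "environmental", "composite"),
) -> pd.DataFrame:
    """Kruskal-Wallis comparison of each score column across group labels.

    Returns one row per score column with H, df, and the asymptotic
    p-value.  Comparisons with fewer than two non-empty groups are skipped
    with a warning (NaN row).
    """
    labels = np.asarray(labels)
    if len(labels) != len(scores):
        raise ValueError("labels must match the score table length")
    present = [g for g in pd.unique(labels)]
    rows = {}
    for col in columns:
        grouped = [scores.loc[labels == g, col].to_numpy() for g in present]
        grouped = [g for g in grouped if g.size > 0]
        if len(grouped) < 2:
            warnings.warn(
                f"{col}: fewer than two non-empty groups; comparison skipped",
                stacklevel=2,
            )
            rows[col] = {"H": np.nan, "df": np.nan, "p_value": np.nan}
            continue
        res = kruskal_wallis(grouped)
        rows[col] = {"H": res.statistic, "df": res.df, "p_value": res.p_value}
    return pd.DataFrame(rows).T
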