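"""Stratified sample-size determination and Neyman allocation.

A survey population is split into homogeneous strata (here: herd-size
classes).  The required total sample size for estimating a population mean
with absolute margin of error ``d`` at normal quantile ``z`` is

    n = (sum_h N_h S_h)^2 / (N^2 D^2 + sum_h N_h S_h^2),   D^2 = d^2 / z^2,

and the Neyman rule allocates n across strata proportionally to N_h S_h,
which minimises the variance of the stratified mean for a fixed n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["StratumSpec", "required_sample_size", "neyman_allocation"]

#: Standard-normal quantile conventionally used for 99% two-sided confidence.
Z_99 = 2.576


@dataclass(frozen=True)
class StratumSpec:
    """One stratum: population count ``Nh`` and within-stratum SD ``Sh``."""

    Nh: int
    Sh: float

    def __post_init__(self) -> None:
        if self.Nh < 1:
            raise ValueError(f"stratum population must be >= 1, got {self.Nh}")
        if self.Sh < 0:
            raise ValueError(f"stratum SD must be >= 0, got {self.Sh}")


def required_sample_size(
    strata: Sequence[StratumSpec], z: float = Z_99, d: float = 0.1
) -> int:
    """Total sample size for a stratified design, rounded up.

    Parameters
    ----------
    strata
        Stratum specifications (``Nh``, ``Sh``).
    z
        Standard-normal quantile for the confidence level (2.576 for 99%).
    d
        Absolute margin of error, in the units of the stratification variable.

    Returns
    -------
    int
        ``ceil`` of the continuous solution; 0 (with a warning) when every
        stratum has zero variance, since there is nothing to estimate.
    """
    if not strata:
        raise ValueError("at least one stratum is required")
    if d <= 0 or z <= 0:
        raise ValueError("d and z must be positive")
    Nh = np.array([s.Nh for s in strata], dtype=float)
    Sh = np.array([s.Sh for s in strata], dtype=float)
    if np.all(Sh == 0):
        warnings.warn("all strata have zero variance; no sampling needed", stacklevel=2)
        return 0
    N = Nh.sum()
    D2 = (d / z) ** 2
    n = (Nh * Sh).sum() ** 2 / (N**2 * D2 + (Nh * Sh**2).sum())
    return math.ceil(n)


def neyman_allocation(strata: Sequence[StratumSpec], n: int) -> np.ndarray:
    """Allocate ``n`` sample units across strata proportionally to Nh*Sh.

    Rounding uses the largest-remainder method so the allocation sums to
    ``n`` exactly; stratum allocations are capped at the stratum population
    with the excess redistributed among uncapped strata.
    """
    if not strata:
        raise ValueError("at least one stratum is required")
    Nh = np.array([s.Nh for s in strata], dtype=float)
    Sh = np.array([s.Sh for s in strata], dtype=float)
    if n > Nh.sum():
        raise ValueError(f"n={n} exceeds total population {int(Nh.sum())}")
    weights = Nh * Sh
    active = weights > 0
    if n < int(active.sum()):
        raise ValueError(
            f"n={n} is smaller than the number of strata with positive Nh*Sh"
        )
    alloc = np.zeros(len(strata), dtype=int)
    remaining = n
    # Cap-and-redistribute loop: each pass fixes strata whose proportional
    # share exceeds the stratum population.
    while True:
        w = np.where(active, weights, 0.0)
        if w.sum() == 0 or remaining == 0:
            break
        quota = remaining * w / w.sum()
        base = np.floor(quota).astype(int)
        short = remaining - int(base.sum())
        # Largest fractional remainders get the leftover units; ties broken
        # by stratum index for determinism.
        order = np.lexsort((np.arange(len(strata)), -(quota - base)))
        base[order[:short]] += 1
        capped = active & (alloc + base > Nh)
        if not capped.any():
            alloc += base
            break
        alloc[capped] = Nh[capped].astype(int)
        remaining = n - int(alloc.sum())
        active = active & ~capped
    return alloc
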