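"""Directional min-max normalization of sustainability indicators,
per-dimension index construction, threshold classification, and scale
reliability (Cronbach's alpha).

Each indicator has a dimension (economic / social / environmental) and a
direction: for a "higher is better" indicator the normalised value is
(x - min) / (max - min), for a "lower is better" one it is
(max - x) / (max - min), both computed against the observed sample range.
A dimension index is the unweighted mean of its normalised indicators; the
weighted combination across dimensions lives in :mod:`farmsustain.ahp`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IndicatorDef",
    "NormalizedTable",
    "DIMENSIONS",
    "SUSTAINABILITY_CLASSES",
    "load_schema",
    "normalize",
    "dimension_index",
    "classify_sustainability",
    "cronbach_alpha",
]

DIMENSIONS = ("economic", "social", "environmental")
_SCALES = ("binary", "likert5", "frequency6", "continuous")

#: Class label -> (lower, upper] interval of the composite/dimension score.
#: The bottom class is closed at 0 so the partition covers [0, 1].
SUSTAINABILITY_CLASSES = (
    ("Unacceptable", 0.00, 0.20),
    ("Borderline", 0.20, 0.40),
    ("Average", 0.40, 0.60),
    ("Good", 0.60, 0.80),
    ("Best", 0.80, 1.00),
)


@dataclass(frozen=True)
class IndicatorDef:
    name: str
    dimension: str
    direction: int
    scale: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r} for {self.name}")
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1 or -1 for {self.name}")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r} for {self.name}")


@dataclass(frozen=True)
class NormalizedTable:
    """Normalised indicator matrix (farms x indicators, values in [0,1])
    plus the observed per-indicator min/max used for the scaling."""

    lij: pd.DataFrame
    provenance: pd.DataFrame  # columns: min, max, direction


def load_schema(path: str | Path | None = None) -> list[IndicatorDef]:
    """Load an indicator schema from YAML; defaults to the packaged schema."""
    if path is None:
        text = (
            resources.files("farmsustain").joinpath("data/indicator_schema.yaml")
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    defs = [IndicatorDef(**entry) for entry in raw["indicators"]]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("indicator names must be unique")
    return defs


def normalize(values: pd.DataFrame, defs: Sequence[IndicatorDef]) -> NormalizedTable:
    """Directional min-max normalisation of raw indicator columns.

    Missing values are imputed by the indicator median (count reported via
    a warning).  Constant columns carry no ordering information and map to
    the neutral value 0.5 for every farm, again with a warning.
    """
    missing_cols = [d.name for d in defs if d.name not in values.columns]
    if missing_cols:
        raise KeyError(f"indicator columns absent from data: {missing_cols}")
    out = {}
    prov = {}
    for d in defs:
        col = pd.to_numeric(values[d.name], errors="coerce").astype(float)
        if col.isna().all():
            raise ValueError(f"indicator {d.name!r} has no non-missing values")
        n_missing = int(col.isna().sum())
        if n_missing:
            warnings.warn(
                f"indicator {d.name!r}: imputed {n_missing} missing value(s) "
                "with the median",
                stacklevel=2,
            )
            col = col.fillna(col.median())
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            warnings.warn(
                f"indicator {d.name!r} is constant; normalised to neutral 0.5",
                stacklevel=2,
            )
            out[d.name] = pd.Series(0.5, index=col.index)
        elif d.direction == 1:
            out[d.name] = (col - lo) / (hi - lo)
        else:
            out[d.name] = (hi - col) / (hi - lo)
        prov[d.name] = {"min": lo, "max": hi, "direction": d.direction}
    lij = pd.DataFrame(out, index=values.index)
    return NormalizedTable(lij=lij, provenance=pd.DataFrame(prov).T)


def dimension_index(
    normalized: NormalizedTable, defs: Sequence[IndicatorDef], dimension: str
) -> pd.Series:
    """Per-farm dimension index: unweighted mean of the dimension's
    normalised indicators."""
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    cols = [d.name for d in defs if d.dimension == dimension]
    if not cols:
        raise ValueError(f"no indicators defined for dimension {dimension!r}")
    return normalized.lij[cols].mean(axis=1).rename(dimension)


def classify_sustainability(score: float) -> str:
    """Map a [0,1] sustainability score to its qualitative class."""
    if not np.isfinite(score) or score < 0 or score > 1:
        raise ValueError(f"sustainability score must lie in [0, 1], got {score}")
    for label, lo, hi in SUSTAINABILITY_CLASSES:
        if score <= hi or label == "Best":
            return label
    raise AssertionError("unreachable")


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with sample (n-1) variances.  Requires >= 2 items, >= 3 respondents,
    and a non-constant total score.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D table with at least two items")
    if x.shape[0] < 3:
        raise ValueError("need at least three respondents")
    if np.isnan(x).any():
        raise ValueError("missing values are not supported; impute first")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score is constant; alpha is undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1 - item_var / total_var)
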