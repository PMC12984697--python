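"""Synthetic farm populations with known ground truth.

Survey microdata of the kind this pipeline analyses are rarely shareable,
so the generator builds farm populations with the statistical structure
the analysis assumes, which makes every downstream stage testable against
a known truth:

* Production follows a Cobb-Douglas frontier over five inputs (roughage,
  concentrate, herd size in livestock units, labor, veterinary spending)
  with elasticities summing to less than one, so the production set is
  convex and a variable-returns-to-scale DEA frontier is the right
  benchmark.  Observed output is frontier output times the farm's true
  efficiency.
* True efficiency is e = clip(1 - u + x'beta + sigma*eps, floor, 1),
  where u is half-normal "managerial" inefficiency and x'beta shifts the
  latent score by centered socio-economic covariates.  The clip at 1
  produces an exact point mass of fully efficient farms (the
  right-censoring a two-limit Tobit expects).
* Input magnitudes are lognormal with a shared farm-size factor, matched
  to published smallholder buffalo survey moments; output is rescaled so
  the sample mean gross production value (GPV) hits the survey mean
  (input-oriented DEA scores are invariant to output scaling).
* Sustainability indicators are drawn from per-indicator priors,
  independent of efficiency by default -- the "no linkage" null under
  which efficiency groups should not differ in sustainability.

All randomness flows from one seed through named spawned substreams, so
adding draws to one block never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ahp import PairwiseMatrix
from .sampling import StratumSpec

__all__ = [
    "GeneratorConfig",
    "FarmData",
    "DEA_INPUT_COLUMNS",
    "TOBIT_COVARIATES",
    "generate_farms",
    "generate_expert_matrices",
    "generate_population_strata",
    "simulate_tobit",
    "write_farm_table",
    "write_expert_matrices",
]

DEA_INPUT_COLUMNS = ("roughage_kg", "concentrate_kg", "livestock_units", "labor_hours", "vet_cost")
TOBIT_COVARIATES = (
    "plant_experience_years",
    "nonfarm_income",
    "livestock_experience_years",
    "education_level",
    "indebted",
    "computer",
    "internet",
)

#: Published survey moments the covariate block is centered on.
COVARIATE_REF_MEANS = {
    "plant_experience_years": 32.750,
    "nonfarm_income": 0.486,
    "livestock_experience_years": 32.458,
    "education_level": 2.556,
    "indebted": 0.708,
    "computer": 0.625,
    "internet": 0.750,
}

#: Survey moments (mean, coefficient of variation) for the DEA inputs,
#: plus the zero-inflation probability and placeholder value for inputs
#: whose survey minimum is (near) zero.
_INPUT_MOMENTS = {
    "roughage_kg": (39833.970, 1.8352, 0.0, None),
    "concentrate_kg": (13151.112, 1.5309, 0.06, 0.01),
    "livestock_units": (22.365, 0.8244, 0.0, None),
    "labor_hours": (1614.254, 0.8078, 0.0, None),
    "vet_cost": (509.967, 0.6347, 0.04, 0.0),
}

#: Default latent-efficiency slopes (per raw covariate unit) and noise SD.
DEFAULT_TOBIT_TRUTH = {
    "slopes": {
        "plant_experience_years": -0.014,
        "nonfarm_income": 0.255,
        "livestock_experience_years": 0.016,
        "education_level": -0.059,
        "indebted": -0.203,
        "computer": -0.118,
        "internet": 0.176,
    },
    "sigma": 0.12,
}

# Per-indicator sampling priors.  "bernoulli": p; "categorical": class
# probabilities on the scale's support; "normal": (mean, sd, lo, hi);
# "lognormal": (mean, cv); "poisson": rate; "derived" columns are computed
# from the farm economics.
DEFAULT_INDICATOR_PRIORS: dict[str, tuple] = {
    "gross_production_value": ("derived",),
    "relative_profit": ("derived",),
    "absolute_profit": ("derived",),
    "livestock_units": ("derived",),
    "production_cost": ("derived",),
    "milk_yield": ("normal", 900.0, 250.0, 300.0, 1800.0),
    "lactation_period": ("normal", 220.0, 30.0, 150.0, 300.0),
    "animal_deaths": ("poisson", 0.6),
    "forage_crop_production": ("bernoulli", 0.90),
    "savings_status": ("bernoulli", 0.32),
    "indoor_feeding_period": ("normal", 170.0, 35.0, 90.0, 270.0),
    "record_keeping": ("bernoulli", 0.17),
    "pasture_feeding": ("bernoulli", 0.75),
    "manager_age": ("normal", 50.0, 11.0, 25.0, 75.0),
    "education_duration": ("derived",),
    "experience_years": ("derived",),
    "institution_communication": ("categorical", (0.10, 0.25, 0.30, 0.20, 0.10, 0.05)),
    "extension_participation": ("categorical", (0.90, 0.06, 0.02, 0.01, 0.005, 0.005)),
    "organization_membership": ("bernoulli", 0.94),
    "social_life_satisfaction": ("bernoulli", 0.17),
    "social_activities": ("bernoulli", 0.07),
    "healthcare_access": ("bernoulli", 0.81),
    "education_access": ("bernoulli", 0.68),
    "transport_infrastructure": ("bernoulli", 0.76),
    "veterinary_access": ("bernoulli", 0.99),
    "farming_satisfaction": ("categorical", (0.05, 0.10, 0.25, 0.40, 0.20)),
    "farming_interest": ("categorical", (0.05, 0.15, 0.25, 0.35, 0.20)),
    "communication_tool_use": ("categorical", (0.20, 0.35, 0.25, 0.12, 0.05, 0.03)),
    "family_opinion_importance": ("categorical", (0.01, 0.02, 0.07, 0.30, 0.60)),
    "family_contribution_importance": ("categorical", (0.02, 0.05, 0.25, 0.45, 0.23)),
    "family_continuation_willingness": ("bernoulli", 0.19),
    "pasture_adequacy": ("bernoulli", 0.44),
    "pasture_reduction": ("bernoulli", 0.54),
    "pasture_quality": ("bernoulli", 0.47),
    "pasture_pressure_on_herd": ("bernoulli", 0.72),
    "biodiversity_importance": ("bernoulli", 0.78),
    "eco_friendly_practices": ("bernoulli", 0.97),
    "equipment_hygiene": ("bernoulli", 0.99),
    "indoor_area_per_animal": ("lognormal", 5.0, 0.5),
    "manure_as_fuel": ("bernoulli", 0.07),
    "shelter_adequacy": ("categorical", (0.10, 0.25, 0.35, 0.25, 0.05)),
    "other_cattle_presence": ("bernoulli", 0.28),
    "manure_pit": ("bernoulli", 0.15),
}

def independent_indicator_priors() -> dict[str, tuple]:
    """Priors with every indicator drawn independently of the production
    block: the zero efficiency-sustainability linkage configuration.

    The default priors derive the economic indicators (GPV, profits, herd
    size, unit cost) and two social ones (education, experience) from the
    farm's production and covariate draws, which couples them to true
    efficiency.  Replacing those with free marginal distributions removes
    every such channel, giving the null under which efficiency groups
    should not differ in sustainability.
    """
    priors = dict(DEFAULT_INDICATOR_PRIORS)
    priors.update(
        {
            "gross_production_value": ("lognormal", 13800.569, 0.707),
            "relative_profit": ("normal", 170.0, 150.0, -400.0, 800.0),
            "absolute_profit": ("normal", 3800.0, 3000.0, -5000.0, 20000.0),
            # livestock_units stays the physical herd-size column: it is
            # the same survey variable the DEA input uses.
            "production_cost": ("lognormal", 450.0, 0.4),
            "education_duration": ("normal", 8.0, 3.0, 0.0, 15.0),
            "experience_years": ("normal", 32.5, 13.5, 5.0, 55.0),
        }
    )
    return priors


#: Education level (0-5 categorical) -> years of schooling.
_EDUCATION_YEARS = np.array([0.0, 5.0, 8.0, 11.0, 13.0, 15.0])

_SAATY_GRID = np.concatenate([1.0 / np.arange(9, 1, -1), np.arange(1, 10, dtype=float)])


@dataclass
class GeneratorConfig:
    """Knobs of the farm-population generator.

    Defaults emulate a 72-farm smallholder buffalo survey: input and
    covariate moments match the published summary tables, and the default
    inefficiency scale / latent slopes put roughly a fifth of farms on
    the frontier (the published right-censoring pattern).
    """

    n_farms: int = 72
    n_strata: int = 4
    production_elasticities: Mapping[str, float] = field(
        default_factory=lambda: {
            "roughage_kg": 0.15,
            "concentrate_kg": 0.10,
            "livestock_units": 0.45,
            "labor_hours": 0.15,
            "vet_cost": 0.05,
        }
    )
    inefficiency_scale: float = 0.3
    tobit_truth: Mapping = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_TOBIT_TRUTH)))
    indicator_priors: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_PRIORS)
    )
    efficiency_floor: float = 0.05
    # Log-input loading on the common farm-size factor: feed, labor and
    # veterinary spending scale almost proportionally with herd size.
    input_correlation: float = 0.9
    experience_correlation: float = 0.8
    target_mean_gpv: float = 13800.569
    seed: int = 20240201

    def __post_init__(self) -> None:
        if self.n_farms < 1 or self.n_strata < 1 or self.n_farms < self.n_strata:
            raise ValueError("need n_farms >= n_strata >= 1")
        if any(v < 0 for v in self.production_elasticities.values()):
            raise ValueError("production elasticities must be nonnegative")
        if self.inefficiency_scale < 0:
            raise ValueError("inefficiency_scale must be >= 0")
        if not 0 < self.efficiency_floor < 1:
            raise ValueError("efficiency_floor must lie in (0, 1)")
        for name, prior in self.indicator_priors.items():
            kind = prior[0]
            if kind == "bernoulli" and not 0 <= prior[1] <= 1:
                raise ValueError(f"invalid Bernoulli p for {name}")
            if kind == "categorical":
                probs = np.asarray(prior[1], dtype=float)
                if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
                    raise ValueError(f"invalid categorical probabilities for {name}")


@dataclass
class FarmData:
    """Generated farm table plus the generator's hidden truth."""

    frame: pd.DataFrame
    true_efficiency: np.ndarray
    truth: dict


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    s2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - s2 / 2.0
    return np.exp(mu + np.sqrt(s2) * rng.standard_normal(size))


def generate_farms(config: GeneratorConfig | None = None) -> FarmData:
    """Draw a farm population with known true efficiencies."""
    cfg = config or GeneratorConfig()
    n = cfg.n_farms
    rng_cov, rng_ineff, rng_input, rng_ind = _spawn(cfg.seed, 4)

    # --- socio-economic covariates ---------------------------------------
    rho = cfg.experience_correlation
    z1 = rng_cov.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng_cov.standard_normal(n)
    plant = np.clip(32.750 + 12.683 * z1, 0.0, 51.0)
    livestock = np.clip(32.458 + 13.457 * z2, 5.0, 55.0)
    edu = rng_cov.choice(6, size=n, p=(0.02, 0.10, 0.33, 0.42, 0.08, 0.05)).astype(float)
    nonfarm = (rng_cov.random(n) < 0.486).astype(float)
    debt = (rng_cov.random(n) < 0.708).astype(float)
    computer = (rng_cov.random(n) < 0.625).astype(float)
    internet = (rng_cov.random(n) < 0.750).astype(float)
    cov = pd.DataFrame(
        {
            "plant_experience_years": plant,
            "nonfarm_income": nonfarm,
            "livestock_experience_years": livestock,
            "education_level": edu,
            "indebted": debt,
            "computer": computer,
            "internet": internet,
        }
    )

    # --- true efficiency ---------------------------------------------------
    slopes = cfg.tobit_truth["slopes"]
    sigma_t = float(cfg.tobit_truth["sigma"])
    shift = np.zeros(n)
    for name in TOBIT_COVARIATES:
        shift += slopes.get(name, 0.0) * (cov[name].to_numpy() - COVARIATE_REF_MEANS[name])
    u = np.abs(rng_ineff.standard_normal(n)) * cfg.inefficiency_scale
    eps = rng_ineff.standard_normal(n)
    latent = 1.0 - u + shift + sigma_t * eps
    efficiency = np.clip(latent, cfg.efficiency_floor, 1.0)

    # --- DEA inputs and output --------------------------------------------
    size_factor = rng_input.standard_normal(n)
    rho_in = cfg.input_correlation
    inputs = {}
    for col, (mean, cv_, p_zero, placeholder) in _INPUT_MOMENTS.items():
        s2 = np.log(1.0 + cv_**2)
        mu = np.log(mean) - s2 / 2.0
        zz = rho_in * size_factor + np.sqrt(1 - rho_in**2) * rng_input.standard_normal(n)
        vals = np.exp(mu + np.sqrt(s2) * zz)
        if p_zero > 0:
            mask = rng_input.random(n) < p_zero
            vals = vals / (1.0 - p_zero)  # keep the unconditional mean
            vals[mask] = placeholder
        inputs[col] = vals
    x = pd.DataFrame(inputs)

    alphas = cfg.production_elasticities
    log_frontier = np.zeros(n)
    for col, a in alphas.items():
        log_frontier += a * np.log(np.maximum(x[col].to_numpy(), 0.01))
    frontier = np.exp(log_frontier)
    gpv = frontier * efficiency
    scale = cfg.target_mean_gpv / gpv.mean()  # output units; DEA-invariant
    gpv = gpv * scale

    # --- sustainability indicators ----------------------------------------
    cost_per_lu = _lognormal(rng_ind, 450.0, 0.4, n)
    total_cost = cost_per_lu * x["livestock_units"].to_numpy()
    derived = {
        "gross_production_value": gpv,
        "livestock_units": x["livestock_units"].to_numpy(),
        "relative_profit": (gpv - total_cost) / x["livestock_units"].to_numpy(),
        "absolute_profit": gpv - total_cost,
        "production_cost": cost_per_lu,
        "education_duration": _EDUCATION_YEARS[edu.astype(int)],
        "experience_years": livestock,
    }
    indicators = {}
    for name, prior in cfg.indicator_priors.items():
        kind = prior[0]
        if kind == "derived":
            indicators[name] = derived[name]
        elif kind == "bernoulli":
            indicators[name] = (rng_ind.random(n) < prior[1]).astype(float)
        elif kind == "categorical":
            probs = np.asarray(prior[1], dtype=float)
            indicators[name] = rng_ind.choice(len(probs), size=n, p=probs) + 1.0
        elif kind == "normal":
            _, mean, sd, lo, hi = prior
            indicators[name] = np.clip(mean + sd * rng_ind.standard_normal(n), lo, hi)
        elif kind == "lognormal":
            indicators[name] = _lognormal(rng_ind, prior[1], prior[2], n)
        elif kind == "poisson":
            indicators[name] = rng_ind.poisson(prior[1], size=n).astype(float)
        else:
            raise ValueError(f"unknown prior kind {kind!r} for indicator {name}")

    base = pd.concat(
        [pd.DataFrame({"farm_id": [f"farm{j + 1:03d}" for j in range(n)], "gpv": gpv}), x, cov],
        axis=1,
    )
    # An indicator may coincide with a DEA/covariate column (e.g. herd size
    # in livestock units); keep the single shared column.
    fresh = {k: v for k, v in indicators.items() if k not in base.columns}
    frame = pd.concat([base, pd.DataFrame(fresh)], axis=1)
    truth = {
        "seed": cfg.seed,
        "inefficiency_scale": cfg.inefficiency_scale,
        "tobit_truth": {"slopes": dict(slopes), "sigma": sigma_t},
        "efficiency_floor": cfg.efficiency_floor,
        "output_scale": float(scale),
        "true_efficiency": efficiency.tolist(),
    }
    return FarmData(frame=frame, true_efficiency=efficiency, truth=truth)


def generate_expert_matrices(
    n_experts: int,
    true_weights: Sequence[float],
    perturbation_sd: float = 0.1,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> list[PairwiseMatrix]:
    """Expert pairwise matrices around a known weight vector.

    Each upper-triangle entry is w_i/w_j times lognormal noise, snapped to
    the nearest admissible Saaty value in {1/9..1/2, 1..9}; the lower
    triangle is the exact reciprocal.
    """
    w = np.asarray(true_weights, dtype=float)
    if (w <= 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("true_weights must be positive and sum to 1")
    if perturbation_sd < 0:
        raise ValueError("perturbation_sd must be >= 0")
    k = w.size
    lbl = tuple(labels) if labels else tuple(f"c{i + 1}" for i in range(k))
    rng = np.random.Generator(np.random.PCG64(seed))
    out = []
    for _ in range(n_experts):
        a = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                raw = (w[i] / w[j]) * np.exp(perturbation_sd * rng.standard_normal())
                snapped = _SAATY_GRID[np.argmin(np.abs(np.log(_SAATY_GRID) - np.log(raw)))]
                a[i, j] = snapped
                a[j, i] = 1.0 / snapped
        out.append(PairwiseMatrix(a, lbl))
    return out


def generate_population_strata(
    n_strata: int, sizes: Sequence[int], sds: Sequence[float]
) -> list[StratumSpec]:
    """Build stratum specifications from parallel size and SD vectors."""
    if n_strata < 1:
        raise ValueError("need at least one stratum")
    if len(sizes) != n_strata or len(sds) != n_strata:
        raise ValueError("sizes and sds must each have length n_strata")
    return [StratumSpec(Nh=int(N), Sh=float(S)) for N, S in zip(sizes, sds)]


def simulate_tobit(
    n: int,
    beta: Sequence[float],
    sigma: float,
    seed: int = 0,
    lower: float = 0.0,
    upper: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-limit Tobit draw: X = [1, N(0,1) slopes], y = clip(Xb + s*eps).

    Returns ``(y, X)``; used for parameter-recovery and size/power studies.
    """
    b = np.asarray(beta, dtype=float)
    rng = np.random.Generator(np.random.PCG64(seed))
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(b.size - 1)])
    y_star = X @ b + sigma * rng.standard_normal(n)
    return np.clip(y_star, lower, upper), X


def write_farm_table(data: FarmData, csv_path: str | Path) -> Path:
    """Write the farm table as CSV plus a JSON sidecar of generator truth."""
    csv_path = Path(csv_path)
    data.frame.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(data.truth, indent=2))
    return csv_path


def write_expert_matrices(matrices: Sequence[PairwiseMatrix], path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "labels": list(matrices[0].labels),
        "matrices": [m.values.tolist() for m in matrices],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path
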