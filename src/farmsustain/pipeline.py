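"""End-to-end orchestration: simulate (or load) -> DEA -> dimension
indices -> AHP-weighted composite index -> group comparison -> Tobit.

``run_all`` produces a run directory containing per-farm results, the
group-mean and rank-test tables, the regression table, and a single
machine-readable ``summary.json`` that every CSV is a view of.  ``report``
renders the summary as Markdown plus an efficiency-vs-sustainability
scatter with a descriptive OLS line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ahp import PairwiseMatrix, aggregate_judgments, composite_index, consistency, priority_weights
from .dea import DEAProblem, classify_groups, solve_input_oriented, summarize_scores, GROUP_LABELS
from .group_comparison import compare_sustainability_by_group
from .sustainability_index import (
    classify_sustainability,
    cronbach_alpha,
    dimension_index,
    load_schema,
    normalize,
)
from .synthetic import (
    DEA_INPUT_COLUMNS,
    TOBIT_COVARIATES,
    GeneratorConfig,
    generate_farms,
)
from . import tobit as tobit_mod

log = logging.getLogger("farmsustain")

__all__ = ["RunConfig", "run_all", "report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 20240201
    n_farms: int = 72
    farm_csv: str | None = None  # load instead of simulate when set
    rts: str = "vrs"
    group_thresholds: tuple[float, float] = (0.50, 0.75)
    schema_path: str | None = None
    # Either fixed dimension weights (economic, environmental, social) or a
    # JSON file of expert pairwise matrices.
    dimension_weights: tuple[float, float, float] | None = None
    expert_matrices: str | None = None
    weight_method: str = "row_average"
    tobit_covariates: tuple[str, ...] = TOBIT_COVARIATES
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.group_thresholds[0] < self.group_thresholds[1]:
            raise ValueError("group thresholds must be strictly increasing")
        if self.dimension_weights is not None and self.expert_matrices is not None:
            raise ValueError("give fixed weights or expert matrices, not both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "group_thresholds" in raw:
            raw["group_thresholds"] = tuple(raw["group_thresholds"])
        if "dimension_weights" in raw and raw["dimension_weights"] is not None:
            raw["dimension_weights"] = tuple(raw["dimension_weights"])
        if "tobit_covariates" in raw:
            raw["tobit_covariates"] = tuple(raw["tobit_covariates"])
        return cls(**raw)


def _resolve_weights(config: RunConfig) -> tuple[np.ndarray, dict]:
    if config.dimension_weights is not None:
        w = np.asarray(config.dimension_weights, dtype=float)
        return w / w.sum(), {"source": "fixed", "weights": (w / w.sum()).tolist()}
    if config.expert_matrices is not None:
        payload = json.loads(Path(config.expert_matrices).read_text())
        labels = tuple(payload.get("labels", ()))
        mats = [PairwiseMatrix(np.array(m), labels) for m in payload["matrices"]]
        agg = aggregate_judgments(mats)
        w = priority_weights(agg, method=config.weight_method)
        diag = consistency(agg, w)
        return w, {
            "source": "expert_matrices",
            "n_experts": len(mats),
            "weights": w.tolist(),
            "lambda_max": diag.lambda_max,
            "ci": diag.ci,
            "cr": diag.cr,
        }
    # Default: the worked-example dimension weights (economic,
    # environmental, social).
    w = np.array([0.49, 0.31, 0.20])
    w = w / w.sum()
    return w, {"source": "default", "weights": w.tolist()}


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every pipeline stage and write the run directory."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.farm_csv:
            farms = pd.read_csv(config.farm_csv)
        else:
            gen = GeneratorConfig(n_farms=config.n_farms, seed=config.seed)
            farms = generate_farms(gen).frame
        log.info("stage %s: %d farms (seed=%d)", stage, len(farms), config.seed)

        stage = "dea"
        problem = DEAProblem(
            inputs=farms[list(DEA_INPUT_COLUMNS)].to_numpy(),
            outputs=farms["gpv"].to_numpy(),
            rts=config.rts,
        )
        dea_res = solve_input_oriented(problem)
        groups = classify_groups(dea_res.theta, config.group_thresholds)
        score_summary = summarize_scores(dea_res.theta, config.group_thresholds)

        stage = "index"
        defs = load_schema(config.schema_path)
        norm = normalize(farms, defs)
        esi = dimension_index(norm, defs, "economic")
        ssi = dimension_index(norm, defs, "social")
        ensi = dimension_index(norm, defs, "environmental")
        likert_cols = [d.name for d in defs if d.scale in ("likert5", "frequency6")]
        alpha = cronbach_alpha(farms[likert_cols]) if len(likert_cols) >= 2 else None

        stage = "ahp"
        weights, weight_info = _resolve_weights(config)
        csi = composite_index(esi.to_numpy(), ensi.to_numpy(), ssi.to_numpy(), weights)
        classes = [classify_sustainability(v) for v in csi]

        stage = "compare"
        scores = pd.DataFrame(
            {"economic": esi, "social": ssi, "environmental": ensi, "composite": csi},
            index=farms.index,
        )
        kw_table = compare_sustainability_by_group(scores, groups)

        stage = "tobit"
        X = np.column_stack(
            [np.ones(len(farms))] + [farms[c].to_numpy(dtype=float) for c in config.tobit_covariates]
        )
        names = ("const",) + tuple(config.tobit_covariates)
        fit = tobit_mod.fit(dea_res.theta, X, names=names)
        null = tobit_mod.fit(dea_res.theta, np.ones((len(farms), 1)), names=("const",))
        lr = tobit_mod.lr_test(fit, null)
        vifs = tobit_mod.vif(X, names=names)
        white = tobit_mod.white_test(dea_res.theta - X @ fit.beta, X)

        stage = "write"
        results = pd.DataFrame(
            {
                "farm_id": farms["farm_id"] if "farm_id" in farms else np.arange(len(farms)),
                "theta": dea_res.theta,
                "group": groups,
                "esi": esi,
                "ssi": ssi,
                "ensi": ensi,
                "csi": csi,
                "class": classes,
                "peers": [";".join(map(str, p)) for p in dea_res.peers],
            }
        )
        results.to_csv(outdir / "results.csv", index=False)

        group_means = (
            scores.assign(group=groups)
            .groupby("group")
            .mean()
            .reindex([g for g in GROUP_LABELS if g in set(groups)])
        )
        group_means.loc["all_farms"] = scores.mean()
        group_means.to_csv(outdir / "group_means.csv")
        kw_table.to_csv(outdir / "kruskal_wallis.csv")

        tobit_table = pd.DataFrame(
            {
                "variable": fit.names,
                "coefficient": fit.beta,
                "std_error": fit.se,
                "z": fit.z,
                "p": fit.p,
                "ame": fit.ames,
            }
        )
        tobit_table.to_csv(outdir / "tobit.csv", index=False)

        summary = {
            "version": __version__,
            "seed": config.seed,
            "n_farms": int(len(farms)),
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            "efficiency": score_summary,
            "group_sizes": {g: int((groups == g).sum()) for g in GROUP_LABELS},
            "dimension_means": {k: float(scores[k].mean()) for k in scores.columns},
            "csi_class_counts": {c: classes.count(c) for c in sorted(set(classes))},
            "cronbach_alpha_likert": alpha,
            "weights": weight_info,
            "kruskal_wallis": {
                k: {kk: (None if pd.isna(vv) else float(vv)) for kk, vv in row.items()}
                for k, row in kw_table.to_dict("index").items()
            },
            "tobit": {
                "coefficients": dict(zip(fit.names, fit.beta.tolist())),
                "se": dict(zip(fit.names, fit.se.tolist())),
                "ames": {
                    k: (None if np.isnan(v) else float(v))
                    for k, v in zip(fit.names, fit.ames)
                },
                "sigma": fit.sigma,
                "log_likelihood": fit.log_likelihood,
                "n_right_censored": fit.n_right,
                "n_left_censored": fit.n_left,
                "n_uncensored": fit.n_uncensored,
                "lr_chi2": lr.statistic,
                "lr_df": lr.df,
                "lr_p": lr.p_value,
                "vif": {k: (None if np.isinf(v) else float(v)) for k, v in vifs.items()},
                "white_stat": white.statistic,
                "white_p": white.p_value,
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": summary["config_hash"],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:  # annotate the failing stage, then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def report(run_dir: str | Path) -> Path:
    """Render a human-readable report from a completed run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    results_path = run_dir / "results.csv"
    if not summary_path.exists() or not results_path.exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run directory")
    summary = json.loads(summary_path.read_text())
    results = pd.read_csv(results_path)

    theta = results["theta"].to_numpy()
    csi = results["csi"].to_numpy()
    slope, intercept = np.polyfit(theta, csi, 1)
    fitted = intercept + slope * theta
    ss_res = np.sum((csi - fitted) ** 2)
    ss_tot = np.sum((csi - csi.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(theta, csi, s=18, alpha=0.7)
    order = np.argsort(theta)
    ax.plot(theta[order], fitted[order], lw=1.2)
    ax.set_xlabel("technical efficiency (theta)")
    ax.set_ylabel("composite sustainability index")
    ax.set_title(f"descriptive OLS fit, R^2 = {r2:.3f}")
    fig.tight_layout()
    fig.savefig(run_dir / "efficiency_vs_csi.png", dpi=120)
    plt.close(fig)

    lines = [
        "# Farm efficiency and sustainability report",
        "",
        f"n = {summary['n_farms']} farms, seed {summary['seed']}",
        "",
        "## Technical efficiency",
        f"mean {summary['efficiency']['mean']:.3f}, "
        f"min {summary['efficiency']['min']:.3f}, "
        f"max {summary['efficiency']['max']:.3f}, "
        f"SD {summary['efficiency']['sd']:.3f}, "
        f"frontier farms {summary['efficiency']['n_frontier']}",
        f"group sizes: {summary['group_sizes']}",
        "",
        "## Sustainability",
        f"dimension means: "
        + ", ".join(f"{k} {v:.3f}" for k, v in summary["dimension_means"].items()),
        f"dimension weights ({summary['weights']['source']}): "
        + ", ".join(f"{w:.3f}" for w in summary["weights"]["weights"]),
        "",
        "## Efficiency-group comparison (Kruskal-Wallis)",
    ]
    for dim, row in summary["kruskal_wallis"].items():
        if row["H"] is None:
            lines.append(f"- {dim}: skipped (insufficient groups)")
        else:
            lines.append(f"- {dim}: H = {row['H']:.3f}, df = {int(row['df'])}, p = {row['p_value']:.3f}")
    t = summary["tobit"]
    lines += [
        "",
        "## Tobit determinants of efficiency",
        f"right-censored {t['n_right_censored']} of {summary['n_farms']}, "
        f"logL {t['log_likelihood']:.3f}, LR chi2({t['lr_df']}) = {t['lr_chi2']:.2f} "
        f"(p = {t['lr_p']:.4g})",
        "",
        "## Efficiency vs sustainability",
        f"descriptive OLS R^2 = {r2:.3f} (scatter: efficiency_vs_csi.png)",
        "",
    ]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
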