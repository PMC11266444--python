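"""End-to-end orchestration: generate -> score -> model -> partition ->
progression -> report, from a single config with reproducible seeding.

The single run seed fans out to per-stage child streams inside the cohort
generator (stage-keyed ``SeedSequence``), so stage-level reruns reproduce
the full run's outputs.  Every artifact directory contains a manifest
recording the config hash, seed, package versions, and per-stage status.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .change import change_scores_by_group
from .cohort import CohortConfig, apply_missingness, generate_baseline, generate_longitudinal
from .commonality import run_commonality_by_group
from .io import write_baseline_csv, write_visits_csv
from .mmrm import MmrmSpec, fit_mmrm, predict_trajectory
from .scoring import roc_auc, tertile_rule_from_reference
from .splines import SplineSpec
from .survival import derive_progression_table, progression_by_tertile

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Top-level pipeline configuration (all decision flags surfaced)."""

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    seed: int | None = None  # overrides cohort.seed when given
    tertile_by: str = "ptau217"  # analysis stratification variable
    spline_df: int = 2
    elevated_cl_threshold: float = 33.0
    min_group_n: int = 30
    pvalue_mode: str = "full"
    change_at_observed: bool = False
    consecutive_attended: bool = True
    endpoint_requires_final_scheduled: bool = True
    km_ci: str = "loglog"
    tau_substudy: bool = True
    make_plots: bool = True

    def resolved_cohort(self) -> CohortConfig:
        if self.seed is None:
            return self.cohort
        return self.cohort.model_copy(update={"seed": int(self.seed)})


def demo_config(seed: int = 42, make_plots: bool = True) -> RunConfig:
    """Demonstration study configuration: three 500-participant arms,
    biomarker-graded decline, and strongly collinear amyloid/P-tau217
    within the elevated arms (correlation 0.9 on the transformed scale),
    mirroring the qualitative situation where the blood marker carries the
    predictive signal and amyloid PET adds little unique variance."""
    from .cohort import _DEFAULT_BIOMARKERS, DeclineParams

    biomarkers = {
        arm: (p.model_copy(update={"corr_amyloid_ptau": 0.9}) if arm != "LEARN" else p)
        for arm, p in _DEFAULT_BIOMARKERS.items()
    }
    # decline graded continuously in the blood marker: ~0 / -0.7 / -2 mean
    # week-240 change across the elevated tertiles
    decline = DeclineParams(
        tertile_change_240=(0.0, 0.0, 0.0),
        ptau_gradient_240=-8.0,
        ptau_ref=0.2,
    )
    cohort = CohortConfig(
        n_learn=500, n_placebo=500, n_solanezumab=500, seed=seed,
        biomarker_params=biomarkers, decline_params=decline,
    )
    return RunConfig(cohort=cohort, make_plots=make_plots)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def generate_stage(config: RunConfig, outdir: Path) -> dict:
    cohort_cfg = config.resolved_cohort()
    baseline = generate_baseline(cohort_cfg)
    visits, truth = generate_longitudinal(baseline, cohort_cfg)
    visits = apply_missingness(visits, cohort_cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    write_baseline_csv(baseline, outdir / "baseline.csv")
    write_visits_csv(visits, outdir / "visits.csv")
    (outdir / "ground_truth.json").write_text(truth.to_json())
    return {"baseline": baseline, "visits": visits, "truth": truth}


def analyze_stage(config: RunConfig, baseline: pd.DataFrame, visits: pd.DataFrame,
                  outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}

    # --- stratification: biomarker tertiles on the elevated analysis sample
    a4 = baseline[baseline["arm"] != "LEARN"]
    rule = tertile_rule_from_reference(a4[config.tertile_by], name="A4-analysis")
    group = pd.Series("LEARN", index=baseline.index, dtype=object)
    group.loc[a4.index] = np.asarray(rule.assign(a4[config.tertile_by]).astype(str))
    baseline = baseline.assign(group=group)
    tertiles = baseline.set_index("id")["group"]
    out["tertile_rule"] = rule

    # --- diagnostics: P-tau217 discriminating elevated amyloid
    elevated = baseline["amyloid_cl"] > config.elevated_cl_threshold
    out["ptau_auc"] = roc_auc(baseline["ptau217"], elevated)

    # --- trajectory MMRM for the cognitive composite
    weeks = np.sort(visits.loc[visits["measure"] == "PACC", "week"].unique())
    spline = SplineSpec.from_weeks(weeks, df=config.spline_df)
    spec = MmrmSpec(outcome="PACC", grouping="group", spline=spline)
    fit = fit_mmrm(visits, baseline, spec)
    pred = predict_trajectory(fit)
    pred.to_csv(outdir / "trajectory_predictions.csv", index=False)
    (outdir / "mmrm_fit.json").write_text(json.dumps(fit.to_dict(), indent=1))
    out["mmrm_fit"] = fit
    out["trajectory"] = pred

    # --- step 1: per-arm change scores
    changes, rs_fits = change_scores_by_group(visits, baseline, spline=spline)
    pd.concat(
        [c.assign(arm=a) for a, c in changes.items()], ignore_index=True
    ).to_csv(outdir / "change_scores.csv", index=False)
    out["changes"] = changes
    out["random_slope_fits"] = rs_fits

    # --- step 2: commonality partitions per analysis group
    groups = {
        "LEARN": ("LEARN",),
        "placebo": ("placebo",),
        "solanezumab": ("solanezumab",),
        "A4-combined": ("placebo", "solanezumab"),
        "LEARN+A4": ("LEARN", "placebo", "solanezumab"),
    }
    results = run_commonality_by_group(
        changes, baseline, groups, min_n=config.min_group_n, pvalue_mode=config.pvalue_mode
    )
    if config.tau_substudy:
        sub = baseline[baseline["in_tau_substudy"].fillna(False).astype(bool)]
        if not sub.empty:
            sub_changes = {
                a: c[c["id"].isin(sub["id"])] for a, c in changes.items()
            }
            tau_groups = {
                "tau-substudy-placebo": ("placebo",),
                "tau-substudy-solanezumab": ("solanezumab",),
                "tau-substudy-A4": ("placebo", "solanezumab"),
                "tau-substudy-LEARN": ("LEARN",),
            }
            results.update(
                run_commonality_by_group(
                    sub_changes, sub, tau_groups, include_tau=True,
                    min_n=config.min_group_n, pvalue_mode=config.pvalue_mode,
                )
            )
    summary = pd.concat(
        [r.summary().rename_axis("predictor").reset_index() for r in results.values()],
        ignore_index=True,
    )
    summary.to_csv(outdir / "commonality_summary.tsv", sep="\t", index=False)
    (outdir / "commonality.json").write_text(
        json.dumps(
            {
                label: {
                    "r2_full": r.r2_full,
                    "n": r.n,
                    "coefficients": {
                        ",".join(sorted(
                            r.names[i] for i in range(len(r.names)) if m >> i & 1
                        )): c
                        for m, c in r.coefficients.items()
                    },
                }
                for label, r in results.items()
            },
            indent=1,
        )
    )
    out["commonality"] = results

    # --- progression endpoint and KM by tertile
    cdr = visits[visits["measure"] == "CDR_GS"]
    final_week = float(cdr["week"].max())
    outcomes = derive_progression_table(
        cdr, final_week,
        consecutive_attended=config.consecutive_attended,
        endpoint_requires_final_scheduled=config.endpoint_requires_final_scheduled,
    )
    outcomes.to_csv(outdir / "progression_outcomes.csv", index=False)
    curves, incidence = progression_by_tertile(outcomes, tertiles, final_week, ci=config.km_ci)
    pd.concat([c.to_frame() for c in curves.values()], ignore_index=True).to_csv(
        outdir / "progression_curves.csv", index=False
    )
    incidence.rename_axis("stratum").reset_index().to_csv(
        outdir / "progression_incidence.csv", index=False
    )
    out["km_curves"] = curves
    out["incidence"] = incidence
    out["baseline"] = baseline
    return out


def report_stage(config: RunConfig, analysis: dict, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# Synthetic cohort analysis report", ""]
    rule = analysis["tertile_rule"]
    lines += [
        f"Tertile cutpoints ({config.tertile_by}, elevated-arm analysis sample): "
        f"{rule.lower:.3g} / {rule.upper:.3g}",
        f"P-tau217 AUC for amyloid > {config.elevated_cl_threshold:g} CL: "
        f"{analysis['ptau_auc']:.3f}",
        "",
        "## Modeled week-240 trajectory means (per stratum)",
    ]
    pred = analysis["trajectory"]
    wmax = pred["week"].max()
    for _, r in pred[pred["week"] == wmax].iterrows():
        lines.append(f"- {r['group']}: {r['mean']:.2f} (95% CI {r['lo']:.2f}, {r['hi']:.2f})")
    lines += ["", "## Variance in cognitive change explained (commonality)", ""]
    for label, res in analysis["commonality"].items():
        lines.append(f"- {label}: total R^2 = {res.r2_full:.3f} (n={res.n})")
    lines += ["", "## Cumulative CDR-GS progression by stratum (week "
              f"{int(wmax)})", ""]
    for stratum, v in analysis["incidence"].items():
        lines.append(f"- {stratum}: {100 * v:.1f}%")
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    if config.make_plots:
        _make_plots(analysis, outdir)
    return path


def _make_plots(analysis: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for grp, g in analysis["trajectory"].groupby("group"):
        ax.plot(g["week"], g["mean"], label=str(grp))
        ax.fill_between(g["week"], g["lo"], g["hi"], alpha=0.2)
    ax.set_xlabel("Week"); ax.set_ylabel("Modeled mean PACC"); ax.legend()
    fig.tight_layout(); fig.savefig(outdir / "trajectories.png", dpi=110); plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in analysis["km_curves"].items():
        ax.step(curve.times, 1.0 - curve.survival, where="post", label=label)
    ax.set_xlabel("Week"); ax.set_ylabel("Cumulative CDR-GS progression"); ax.legend()
    fig.tight_layout(); fig.savefig(outdir / "progression.png", dpi=110); plt.close(fig)

    results = analysis["commonality"]
    n = len(results)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 4), sharey=True, squeeze=False)
    for ax, (label, res) in zip(axes[0], results.items()):
        s = res.summary()
        idx = np.arange(len(s))
        ax.bar(idx, s["unique_r2"], label="unique")
        ax.bar(idx, s["common_r2"], bottom=s["unique_r2"], label="common")
        ax.set_xticks(idx)
        ax.set_xticklabels(s.index, rotation=90, fontsize=7)
        ax.set_title(f"{label}\nR²={res.r2_full:.2f}", fontsize=8)
    axes[0][0].set_ylabel("R² in PACC change")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout(); fig.savefig(outdir / "commonality.png", dpi=110); plt.close(fig)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages; partial outputs are kept and the manifest marks the
    failed stage on error."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": int(config.resolved_cohort().seed),
        "versions": {"adtraj": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    result: dict = {}
    try:
        for stage, fn in (
            ("generate", lambda: generate_stage(config, outdir)),
            ("analyze", lambda: analyze_stage(config, result["baseline"],
                                              result["visits"], outdir)),
            ("report", lambda: report_stage(config, result, outdir)),
        ):
            out = fn()
            if isinstance(out, dict):
                result.update(out)
            manifest["stages"][stage] = "ok"
    except Exception as exc:  # noqa: BLE001 — manifest must record the failure
        stage = next((s for s in ("generate", "analyze", "report")
                      if s not in manifest["stages"]), "unknown")
        manifest["stages"][stage] = f"failed: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    result["manifest"] = manifest
    return result
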