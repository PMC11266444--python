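# adtraj

Biomarker-stratified analysis of longitudinal cognitive and functional
decline in preclinical Alzheimer's disease cohorts — built for the
question: *how much of the variation in cognitive change over ~4.5 years
is explained by each baseline biomarker, and how much of that is unique
versus shared?*

The package provides, as a tested library plus CLI:

- a **synthetic cohort generator** emulating a secondary-prevention trial
  (two amyloid-elevated randomized arms) with an amyloid-negative
  observational companion cohort: correlated baseline biomarkers
  (amyloid PET Centiloids, plasma P-tau217, tau PET), 6-monthly PACC and
  annual CDR/CFI/ADL visits over 240 weeks, practice effects,
  biomarker-graded decline, CDR progression, and monotone dropout — with
  ground truth recorded for recovery tests;
- **scoring**: PACC z-composite, combined CFI, SUVr→Centiloid
  calibration, tertile assignment, Mann–Whitney ROC AUC;
- **trajectory MMRM**: natural cubic splines in time (df = 2) per group
  with a heterogeneous Toeplitz within-participant covariance
  Σ = D·R·D (free SD per visit, correlations by visit lag), fit by
  profiled maximum likelihood, with predicted mean trajectories and 95%
  CIs;
- **change scores**: per-cohort random-intercept/slope mixed models;
  each participant's estimated change from baseline at week 240 is the
  BLUP-based individual prediction [f(240) − f(0)] + b̂₁ᵢ·240;
- **commonality analysis**: all-subsets OLS R² over the ten baseline
  predictors and the inclusion–exclusion partition
  C(A) = −Σ_{B⊆A} (−1)^{|B|} R²(B ∪ (F∖A)), splitting each predictor's
  R² into unique and shared components that sum exactly to the
  full-model R²;
- **progression survival**: the CDR-GS endpoint (two consecutive ratings
  above 0, or an elevated end-of-study rating) and Kaplan–Meier curves
  with Greenwood/log-log CIs per biomarker tertile.

## Worked example

```sh
adtraj all --seed 42 --outdir demo-out
```

or equivalently from Python:

```python
from adtraj.pipeline import demo_config, run_pipeline
result = run_pipeline(demo_config(seed=42), "demo-out")
```

This generates three 500-participant arms with decline graded
continuously in plasma P-tau217 and strongly collinear amyloid/P-tau217,
then runs the full analysis. `demo-out/report.md` from this exact run:

```
Tertile cutpoints (ptau217, elevated-arm analysis sample): 0.229 / 0.352
P-tau217 AUC for amyloid > 33 CL: 0.759

## Modeled week-240 trajectory means (per stratum)
- LEARN: 1.17 (95% CI 0.92, 1.43)
- T1: 0.61 (95% CI 0.30, 0.91)
- T2: -0.28 (95% CI -0.59, 0.02)
- T3: -2.85 (95% CI -3.15, -2.55)

## Variance in cognitive change explained (commonality)
- LEARN: total R^2 = 0.336 (n=500)
- placebo: total R^2 = 0.727 (n=500)
- solanezumab: total R^2 = 0.741 (n=500)
- A4-combined: total R^2 = 0.731 (n=1000)
- LEARN+A4: total R^2 = 0.717 (n=1500)
- tau-substudy-A4: total R^2 = 0.780 (n=330)

## Cumulative CDR-GS progression by stratum (week 240)
- LEARN: 13.6%
- T1: 8.0%
- T2: 24.7%
- T3: 60.8%
```

Reading the numbers: modeled PACC trajectories are ordered by P-tau217
tertile — the top tertile declines ~2.9 z-units below its baseline by
week 240 while the observational cohort ends above baseline (an early
practice effect it never loses). Cumulative progression to a global CDR
above 0 is likewise tertile-ordered, exceeding 50% in the top tertile.
In the pooled commonality partition
(`demo-out/commonality_summary.tsv`), P-tau217 carries the largest
unique R² while amyloid's unique contribution is ≈0 — its predictive
value is entirely shared, because the generator drives decline through
the blood marker and amyloid is only correlated with it. The per-stratum
trajectory, progression and stacked-bar R² figures are written alongside
the CSVs.

The CLI verbs `generate`, `analyze`, `report`, `all` accept `--config
path.json` (a serialized `RunConfig`), `--seed`, `--outdir` and
`--tertile-by {amyloid_cl,ptau217}`; every analysis decision that has a
defensible alternative (quantile convention, p-value mode, endpoint
dating, CI transform, REML, …) is a config flag. Exit codes: 0 success,
1 configuration error, 2 runtime error.

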