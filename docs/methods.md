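# Methods

`adtraj` analyzes longitudinal cognitive and functional decline in
cognitively unimpaired older adults stratified by baseline Alzheimer
biomarkers (amyloid PET in Centiloids, plasma P-tau217, and optionally a
tau PET neocortical composite). This note documents the models, the
synthetic cohort the tests run on, the numerical choices, and the limits
of what the test suite demonstrates.

## Outcome scoring

The cognitive endpoint is the PACC, the sum of four component z-scores
(FCSRT free+total recall 0–96, Logical Memory delayed recall 0–25,
Digit-Symbol substitution, MMSE 0–30), each standardized by the baseline
mean and SD of the analysis sample; lower is worse. A missing component
yields a missing composite — no prorating, because no defensible
prorating weights exist for a 4-component sum. The combined CFI is the
participant total plus the study-partner total (each 0–15). Amyloid SUVr
is mapped to Centiloids by an affine calibration; the default passes
through the elevation cutpoint (SUVr 1.15 ↔ 33 CL) and the
elevated-cohort mean (1.30 ↔ 66.2 CL) and is exactly invertible.
Tertiles use the 1/3 and 2/3 quantiles (linear interpolation) of a
designated reference sample with half-open boundaries [q₁, q₂), T3
closed above; the convention is configurable because printed cutpoints
alone cannot identify the quantile type. ROC AUC is the midrank
Mann–Whitney statistic (ties count ½), identical to exhaustive pairwise
concordance.

## Trajectory model (MMRM)

Group-mean trajectories are fit by a marginal Gaussian model

y_i ~ N(X_i β, Σ[obs_i, obs_i]),  Σ = D R D,

with a per-group intercept, per-group natural cubic spline in time with
df = 2 (boundary knots at the first/last scheduled week, interior knot at
the schedule median — knot positions are configurable since they are not
identified by "two spline terms" alone), and baseline covariates (age,
education, APOE ε4) centered at sample means. D holds one free SD per
scheduled visit; R is Toeplitz in visit *lag* (ρ₀ = 1). Estimation is
maximum likelihood with β profiled out by GLS; REML is available as a
flag but ML is the default so likelihoods remain comparable across
covariance structures (the independence model is the ρ = 0 submodel, so
its maximized likelihood can never exceed the Toeplitz model's).

Numerical choices:

- Lag correlations are parameterized by partial autocorrelations mapped
  through tanh (Durbin–Levinson), so every point of the unconstrained
  search space yields a positive-definite Toeplitz matrix.
- |atanh φ| is capped at 4 (lag correlations ≤ ~0.99933) and per-visit
  log-SDs are bounded within [log sd(y) − 9, log sd(y) + 4]: on small
  samples with dropout the ML surface otherwise has degenerate spikes
  (one visit's SD → 0 while a correlation → 1).
- The final residual quadratic form is recomputed from whitened
  residuals rather than the y'Wy − b'β shortcut, which cancels
  catastrophically when the signal dominates the noise.
- Participants are grouped by missingness pattern; each pattern costs
  one Cholesky factorization per likelihood evaluation. Rows are sorted
  canonically so results are bit-identical under permutation of input
  order.
- Off-schedule weeks are snapped to the nearest scheduled week (the lag
  structure requires a common grid) with a logged warning.
- Singular GLS normal matrices (e.g. a time basis identically zero when
  only one visit is observed) fall back to the minimum-norm solution.

Predicted trajectories hold covariates at analysis-sample means (the
profile is configurable); 95% CIs are mean ± 1.96·√(x'Vx) with V the GLS
coefficient covariance. Weeks beyond the boundary knots extrapolate
linearly (the natural-spline constraint) with a warning.

## Change scores

Per cohort, a linear mixed model with fixed effects for test version and
the two spline terms, plus random intercepts and slopes (ML, via
statsmodels MixedLM; time scaled to 100-week units internally for
conditioning). The participant change score at week 240 is the
empirical-Bayes individual prediction

change_i = [f(240) − f(0)] + b̂₁ᵢ · 240,

with the test version held fixed (version effects cancel). BLUPs are
computed directly from b̂ᵢ = G Zᵢ'(Zᵢ G Zᵢ' + σ²I)⁻¹(yᵢ − Xᵢβ̂), which
remains well conditioned as σ² → 0 (the exact-fit limit, where the
prediction converges to each participant's own least-squares line). An
alternative evaluates the change at each participant's last observed
week (`at_observed=True`); the two differ only when end-of-study visits
are missing.

## Commonality analysis

The R² of the OLS regression of change scores on the ten baseline
predictors (amyloid CL, P-tau217, baseline PACC, baseline CFI, age,
APOE ε4, female sex, education, URG membership, and treatment where both
randomized arms are pooled; plus the tau PET composite in substudy
analyses) is partitioned over all 2^p − 1 predictor subsets by
inclusion–exclusion:

C(A) = − Σ_{B ⊆ A} (−1)^{|B|} R²(B ∪ (F \ A)).

C({i}) is predictor i's unique R²; the partition conserves the full-model
R² exactly. Negative coefficients (suppressor configurations) are
reported as-is — truncating them would break conservation. Complete
cases only (listwise deletion is logged). Per-predictor p-values default
to full-model coefficient t-tests; marginal single-predictor tests are a
flag, since a stacked-bar display with one p per predictor does not
identify which was used. Rank-deficient subsets are solved by
pseudoinverse and flagged. Groups below a configurable minimum n
(default 30) are skipped, which automatically excludes analyses the
design cannot support (e.g. a tau substudy within the amyloid-negative
cohort).

## Progression endpoint and survival

Progression to functional impairment is two consecutive CDR-GS ratings
above 0, or a rating above 0 at the end-of-study assessment. Defaults,
each flag-switchable: "consecutive" means consecutive *attended* annual
assessments (a missed visit does not reset the pair); the event is dated
at the confirming (second) rating; the single-elevated endpoint rule
requires the rating to fall at the scheduled final week (a dropout's
isolated elevated last rating is censored). Curves are Kaplan–Meier
(lifelines) with Greenwood variance and complementary log-log 95% CIs
(bounded in [0, 1]); a plain linear CI is a flag.

## Synthetic cohort generator

The generator emulates a secondary-prevention trial with an
amyloid-negative observational companion: arms LEARN (Aβ−), placebo and
solanezumab (both Aβ+), defaults 553/583/564 participants; PACC every 24
weeks and functional measures every 48 weeks through week 240.

- **Biomarkers.** Per-arm multivariate Gaussian on transformed scales
  (Centiloids; log P-tau217; tau SUVr), truncated at the amyloid
  eligibility threshold (33 CL): elevated arms above, LEARN below. One
  mechanism produces the bimodal amyloid split. Latent moments follow
  the published elevated-cohort summaries (≈66 ± 33 CL; LEARN ≈5 ± 12);
  note the *post-truncation* moments differ from the latent ones by
  construction, so distribution-recovery tests disable truncation. The
  amyloid–P-tau217 correlation (0.6 default, transformed scale) and the
  P-tau217–tau correlation (induced through the shared amyloid factor)
  keep the 3×3 correlation matrix positive definite.
- **Cognitive decline.** PACC = baseline PACC + trajectory·(w/240)² +
  practice effect + b₀ᵢ + b₁ᵢ·w + noise. The trajectory coefficient is a
  per-tertile step by default (T1/T2/T3 within the elevated arms; LEARN
  separate), with an optional continuous component, threshold-linear in
  measured P-tau217 (`ptau_gradient_240 · max(ptau − 0.2, 0)`), used by
  the demonstration configuration: a decline graded smoothly in the
  blood marker is what makes P-tau217 — rather than the
  truncation-separated amyloid variable — the strongest linear predictor
  of change, mirroring the qualitative finding the pipeline is built to
  detect. The practice effect saturates over the first two post-baseline
  cognitive visits (half gain, then full), or follows an explicit
  per-week profile. Test versions cycle A→B→C.
- **Progression.** A discrete-time hazard per annual visit, logistic in
  cohort-standardized log P-tau217 (intercept −3.2, slope 1.4: roughly
  5%/interval at the cohort mean, >13% one SD up — chosen so the top
  tertile exceeds 50% cumulative progression by week 240 while the
  bottom tertile stays under ~10%). The progressed state is absorbing,
  but each post-progression visit reverts to a 0 rating with probability
  0.15 so that isolated elevated ratings occur and both branches of the
  endpoint definition are exercised.
- **Dropout.** Monotone and outcome-independent (MCAR), constant hazard
  per scheduled visit (default 0.02; attrition was not reported
  numerically, so this default is invented). MCAR keeps likelihood-based
  fits unbiased, which is what makes parameter-recovery tests clean.
- **Reproducibility.** One seed fans out to stage-keyed child streams
  (baseline / longitudinal / missingness), so regenerating any stage
  reproduces the full run. Ground truth (random effects, per-participant
  generating change, progression states, hazard parameters) is recorded.

What the generator does **not** emulate: site effects, dose titration,
amyloid-status disclosure effects, pandemic-era interruptions,
outcome-dependent (MAR/MNAR) attrition, and measurement-error structure
in PET quantification. Passing tests therefore demonstrate correctness
of the estimators under a well-specified generating model, not
robustness to the messiness of real trial data.

## Simulation sizes used by the test suite

Recovery and oracle tests are sized to run on one CPU in minutes: the
Wald-coverage study uses 100 replicates of n = 400 participants on a
5-visit schedule with an intercept + two spline coefficients; likelihood
oracles use 20-participant instances with each participant attending ≥3
of 5 visits; the commonality identity sweep uses 1000 random instances
with p ∈ {2…6}, n ∈ {50…500}; the demonstration pipeline uses three
500-participant arms. The Wald band check is a binomial test at 100
replicates: with several simultaneous coefficients its false-alarm
probability is material even for a perfectly calibrated estimator, which
is why the coverage study tests a compact design.

## Known limitations

- The MMRM Wald covariance is the plug-in GLS covariance at the
  estimated Σ; it ignores covariance-parameter uncertainty
  (Kenward–Roger-type corrections are not implemented), giving coverage
  ~94% rather than 95% at n = 400.
- CDR-SB and the other functional scales are modeled as Gaussian
  pseudo-continuous outcomes; no ordinal or censored likelihoods.
- No joint modeling of dropout and outcome; estimates are valid under
  (M)CAR only.
- Commonality analysis is exponential in p (2^p regressions); p = 11 is
  the practical ceiling here, and no bootstrap CIs or dominance-analysis
  variants are provided.
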