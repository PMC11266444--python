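"""Synthetic preclinical-AD cohort generator.

Emulates the statistical structure of a secondary-prevention trial plus
observational companion: three arms (an amyloid-negative observational
cohort "LEARN", and amyloid-elevated "placebo"/"solanezumab" randomized
arms), a cognitive composite (PACC) assessed every 6 months and functional
measures (combined CFI, partner ADL, CDR-SB, CDR global score) annually
over 240 weeks.

Mechanisms:

* Baseline biomarkers (amyloid Centiloid, plasma P-tau217, neocortical tau
  PET SUVr) are drawn from a per-arm multivariate Gaussian on transformed
  scales (log for P-tau217), truncated at the amyloid eligibility
  threshold — elevated arms above it, the observational arm below — which
  reproduces the bimodal amyloid split with a single mechanism.
* PACC trajectories: per-biomarker-tertile fixed decline curves (power law
  in time, anchored at the configured week-240 change), a practice effect
  saturating over the first two post-baseline cognitive visits, Gaussian
  random intercepts/slopes, and i.i.d. residual noise.  Test versions
  cycle A -> B -> C across cognitive visits.
* CDR global score progression: a discrete-time hazard per annual visit,
  logistic in standardized log P-tau217, absorbing once entered (with an
  optional per-visit reversion-to-0 rating probability so that isolated
  elevated ratings occur, as in real CDR series).
* Dropout: monotone, outcome-independent (MCAR) with a constant per-visit
  hazard; week 0 is never removed.

All ground-truth quantities (realized random effects, generating
coefficients, progression states) are recorded for parameter-recovery
tests, and everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .scoring import DEFAULT_CENTILOID, centiloid_to_suvr, tertile_rule_from_reference

ARMS = ("LEARN", "placebo", "solanezumab")
COGNITIVE_MEASURES = ("PACC",)
FUNCTIONAL_MEASURES = ("CFI_combined", "ADL_partner", "CDR_SB", "CDR_GS")
TEST_VERSIONS = ("A", "B", "C")


class BiomarkerArmParams(BaseModel):
    """Joint distribution of baseline biomarkers for one arm, on the
    Gaussian (transformed) scale: amyloid in Centiloids, P-tau217 in log
    assay units, tau PET in SUVr."""

    amyloid_cl_mean: float
    amyloid_cl_sd: float = Field(gt=0)
    log_ptau_mean: float
    log_ptau_sd: float = Field(gt=0)
    corr_amyloid_ptau: float = Field(gt=-1, lt=1)
    tau_suvr_mean: float = 1.2
    tau_suvr_sd: float = Field(default=0.12, gt=0)
    corr_amyloid_tau: float = Field(default=0.5, gt=-1, lt=1)


class DeclineParams(BaseModel):
    """Outcome-trajectory coefficients.

    Week-240 mean changes are per biomarker tertile (T1, T2, T3) within the
    amyloid-elevated arms; the observational arm has its own coefficient.
    Trajectories follow ``change_240 * (week/240)**shape_power`` (power 2:
    accelerating decline).  SDs are in outcome units; the random slope SD
    is per week.
    """

    tertile_change_240: tuple[float, float, float] = (-0.1, -0.8, -2.0)
    learn_change_240: float = 0.0
    #: optional continuous decline component, threshold-linear in measured
    #: plasma P-tau217: extra week-240 change = gradient * max(ptau - ref, 0).
    #: Off by default; when used, decline is graded smoothly in the blood
    #: marker rather than stepping at tertile boundaries.
    ptau_gradient_240: float = 0.0
    ptau_ref: float = 0.2
    shape_power: float = Field(default=2.0, gt=0)
    practice_effect: float = 0.5
    practice_profile: dict[float, float] | None = None
    random_intercept_sd: float = Field(default=0.0, ge=0)
    random_slope_sd: float = Field(default=0.0015, ge=0)
    residual_sd: float = Field(default=0.6, ge=0)
    cfi_tertile_change_240: tuple[float, float, float] = (0.3, 1.0, 2.5)
    cfi_learn_change_240: float = 0.2
    adl_tertile_change_240: tuple[float, float, float] = (-0.2, -0.8, -2.0)
    adl_learn_change_240: float = -0.1
    cdrsb_tertile_change_240: tuple[float, float, float] = (0.05, 0.3, 1.0)
    cdrsb_learn_change_240: float = 0.02
    functional_residual_sd: float = Field(default=0.8, ge=0)

    def practice_gain(self, week: float, cognitive_visit_index: int) -> float:
        if self.practice_profile is not None:
            return float(self.practice_profile.get(week, 0.0))
        return self.practice_effect * min(cognitive_visit_index, 2) / 2.0


class HazardParams(BaseModel):
    """Discrete-time CDR-GS progression hazard per annual visit:
    logit(h_i) = intercept + slope * z_i with z_i the cohort-standardized
    log P-tau217."""

    intercept: float = -3.2
    slope: float = 1.4
    reversion_prob: float = Field(default=0.15, ge=0, le=1)
    cdr_sb_progressed_boost: float = 1.5


class DemographicParams(BaseModel):
    age_mean: float = 71.9
    age_sd: float = Field(default=4.8, gt=0)
    age_range: tuple[float, float] = (65.0, 85.0)
    p_female: float = Field(default=0.58, ge=0, le=1)
    education_mean: float = 16.5
    education_sd: float = Field(default=2.8, gt=0)
    p_apoe4: float = Field(default=0.59, ge=0, le=1)
    p_urg: float = Field(default=0.08, ge=0, le=1)
    pacc_mean: float = 0.0
    pacc_sd: float = Field(default=2.7, gt=0)
    pacc_biomarker_loading: float = -0.4
    cfi_mean: float = 2.3
    cfi_sd: float = Field(default=2.2, gt=0)
    adl_mean: float = 43.5
    adl_sd: float = Field(default=2.6, gt=0)


_DEFAULT_BIOMARKERS = {
    # elevated arms: latent moments follow the published elevated-cohort
    # summaries (mean ~66 CL, SD ~33); the observational arm sits near 0 CL
    "LEARN": BiomarkerArmParams(
        amyloid_cl_mean=4.7, amyloid_cl_sd=12.4,
        log_ptau_mean=-1.72, log_ptau_sd=0.47, corr_amyloid_ptau=0.3,
        tau_suvr_mean=1.10, tau_suvr_sd=0.08, corr_amyloid_tau=0.3,
    ),
    "placebo": BiomarkerArmParams(
        amyloid_cl_mean=65.8, amyloid_cl_sd=32.3,
        log_ptau_mean=-1.39, log_ptau_sd=0.61, corr_amyloid_ptau=0.6,
        tau_suvr_mean=1.20, tau_suvr_sd=0.12, corr_amyloid_tau=0.5,
    ),
    "solanezumab": BiomarkerArmParams(
        amyloid_cl_mean=66.5, amyloid_cl_sd=33.1,
        log_ptau_mean=-1.39, log_ptau_sd=0.61, corr_amyloid_ptau=0.6,
        tau_suvr_mean=1.20, tau_suvr_sd=0.12, corr_amyloid_tau=0.5,
    ),
}

_DEFAULT_DEMOGRAPHICS = {
    "LEARN": DemographicParams(
        age_mean=70.5, age_sd=4.3, p_female=0.62, p_apoe4=0.22,
        pacc_mean=0.9, pacc_sd=2.3, cfi_mean=1.8, cfi_sd=1.9, adl_sd=1.9,
    ),
    "placebo": DemographicParams(p_female=0.60),
    "solanezumab": DemographicParams(p_female=0.57),
}


class CohortConfig(BaseModel):
    """Full generator configuration; defaults emulate the design facts of
    the emulated cohorts (sample sizes of the analysis set, 6-monthly
    cognitive and annual functional schedules over 240 weeks, Table-1-like
    biomarker summaries)."""

    n_learn: int = Field(default=553, ge=0)
    n_placebo: int = Field(default=583, ge=0)
    n_solanezumab: int = Field(default=564, ge=0)
    seed: int = 0
    cognitive_weeks: tuple[float, ...] = tuple(float(w) for w in range(0, 241, 24))
    functional_weeks: tuple[float, ...] = tuple(float(w) for w in range(0, 241, 48))
    biomarker_params: dict[str, BiomarkerArmParams] = Field(
        default_factory=lambda: dict(_DEFAULT_BIOMARKERS)
    )
    demographic_params: dict[str, DemographicParams] = Field(
        default_factory=lambda: dict(_DEFAULT_DEMOGRAPHICS)
    )
    decline_params: DeclineParams = Field(default_factory=DeclineParams)
    hazard_params: HazardParams = Field(default_factory=HazardParams)
    dropout_hazard: float = Field(default=0.02, ge=0, le=1)
    tau_substudy_fraction: float = Field(default=0.33, ge=0, le=1)
    eligibility_threshold_cl: float = 33.0
    truncate_eligibility: bool = True
    tertile_by: str = "ptau217"

    @field_validator("cognitive_weeks", "functional_weeks")
    @classmethod
    def _check_schedule(cls, v):
        w = tuple(float(x) for x in v)
        if not w or w[0] != 0.0:
            raise ValueError("visit schedule must start at week 0")
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValueError("visit weeks must be strictly increasing")
        return w

    @field_validator("tertile_by")
    @classmethod
    def _check_tertile_by(cls, v):
        if v not in ("ptau217", "amyloid_cl"):
            raise ValueError("tertile_by must be 'ptau217' or 'amyloid_cl'")
        return v

    @model_validator(mode="after")
    def _check_counts(self):
        if self.n_learn + self.n_placebo + self.n_solanezumab <= 0:
            raise ValueError("n_learn + n_placebo + n_solanezumab must be positive")
        for arm in ARMS:
            if arm not in self.biomarker_params:
                raise ValueError(f"biomarker_params missing arm {arm!r}")
            if arm not in self.demographic_params:
                raise ValueError(f"demographic_params missing arm {arm!r}")
        return self

    def arm_counts(self) -> dict[str, int]:
        return {"LEARN": self.n_learn, "placebo": self.n_placebo,
                "solanezumab": self.n_solanezumab}


@dataclass
class GroundTruth:
    """Generating quantities recorded for recovery tests."""

    participants: pd.DataFrame  # id, tertile_class, b0, b1, hazard, progression_week
    trajectory_coefficients: dict[str, float]  # class -> week-240 PACC change
    hazard_params: HazardParams
    config: CohortConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "participants": self.participants.to_dict(orient="list"),
                "trajectory_coefficients": self.trajectory_coefficients,
                "hazard_params": self.hazard_params.model_dump(),
                "config": self.config.model_dump(),
            },
            default=str,
        )


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    """Stage-keyed child stream: stage reruns stay reproducible."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), stage]))


def _draw_truncated_mvn(rng, mean, cov, n, cl_low=None, cl_high=None, max_tries=200):
    """Sample MVN rows, rejecting on the first (amyloid CL) coordinate
    until it lies in [cl_low, cl_high]."""
    out = np.empty((n, len(mean)))
    filled = 0
    for _ in range(max_tries):
        if filled >= n:
            break
        draw = rng.multivariate_normal(mean, cov, size=max(n - filled, 1) * 2)
        keep = np.ones(len(draw), dtype=bool)
        if cl_low is not None:
            keep &= draw[:, 0] >= cl_low
        if cl_high is not None:
            keep &= draw[:, 0] < cl_high
        draw = draw[keep]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    if filled < n:
        raise RuntimeError("truncated biomarker sampling failed; threshold too extreme")
    return out


def generate_baseline(config: CohortConfig) -> pd.DataFrame:
    """One row per participant: arm, demographics, biomarker panel, and
    baseline outcome scores.  Deterministic given ``config.seed``."""
    rng = _rng(config, 0)
    rows = []
    counts = config.arm_counts()
    pid = 0
    for arm in ARMS:
        n = counts[arm]
        if n == 0:
            continue
        bm = config.biomarker_params[arm]
        dg = config.demographic_params[arm]
        # 3x3 correlation on (CL, log ptau, tau SUVr); the ptau-tau
        # correlation is induced through the shared amyloid factor
        r_ap, r_at = bm.corr_amyloid_ptau, bm.corr_amyloid_tau
        corr = np.array(
            [[1.0, r_ap, r_at], [r_ap, 1.0, r_ap * r_at], [r_at, r_ap * r_at, 1.0]]
        )
        sds = np.array([bm.amyloid_cl_sd, bm.log_ptau_sd, bm.tau_suvr_sd])
        cov = corr * np.outer(sds, sds)
        mean = np.array([bm.amyloid_cl_mean, bm.log_ptau_mean, bm.tau_suvr_mean])
        lo = hi = None
        if config.truncate_eligibility:
            if arm == "LEARN":
                hi = config.eligibility_threshold_cl
            else:
                lo = config.eligibility_threshold_cl
        draw = _draw_truncated_mvn(rng, mean, cov, n, cl_low=lo, cl_high=hi)
        cl, log_ptau, tau = draw[:, 0], draw[:, 1], draw[:, 2]

        age = np.clip(rng.normal(dg.age_mean, dg.age_sd, n), *dg.age_range)
        female = rng.random(n) < dg.p_female
        education = np.clip(np.round(rng.normal(dg.education_mean, dg.education_sd, n)), 8, 20)
        apoe4 = rng.random(n) < dg.p_apoe4
        urg = rng.random(n) < dg.p_urg
        z_ptau = (log_ptau - bm.log_ptau_mean) / bm.log_ptau_sd
        pacc = dg.pacc_mean + dg.pacc_biomarker_loading * z_ptau + rng.normal(
            0.0, dg.pacc_sd, n
        )
        cfi = np.clip(np.round(rng.normal(dg.cfi_mean, dg.cfi_sd, n) + 0.3 * z_ptau), 0, 30)
        for i in range(n):
            rows.append(
                {
                    "id": f"P{pid:05d}",
                    "arm": arm,
                    "age": float(age[i]),
                    "female": bool(female[i]),
                    "education": float(education[i]),
                    "apoe4_carrier": bool(apoe4[i]),
                    "urg_member": bool(urg[i]),
                    "amyloid_cl": float(cl[i]),
                    "amyloid_suvr": float(centiloid_to_suvr(cl[i], DEFAULT_CENTILOID)),
                    "ptau217": float(np.exp(log_ptau[i])),
                    "tau_neocortical_suvr": float(tau[i]),
                    "baseline_pacc": float(pacc[i]),
                    "baseline_cfi": float(cfi[i]),
                }
            )
            pid += 1
    df = pd.DataFrame(rows)
    # tau PET only in a seeded random substudy subset of the elevated arms
    df["in_tau_substudy"] = False
    a4 = df.index[df["arm"] != "LEARN"]
    k = int(round(config.tau_substudy_fraction * len(a4)))
    if k > 0:
        chosen = rng.choice(a4, size=k, replace=False)
        df.loc[chosen, "in_tau_substudy"] = True
    df.loc[~df["in_tau_substudy"], "tau_neocortical_suvr"] = np.nan
    return df


def _tertile_class(baseline: pd.DataFrame, config: CohortConfig) -> pd.Series:
    """Generator trajectory class: LEARN, or T1/T2/T3 by biomarker tertile
    within the amyloid-elevated arms."""
    cls = pd.Series("LEARN", index=baseline.index, dtype=object)
    a4 = baseline["arm"] != "LEARN"
    if a4.sum() >= 3:
        vals = baseline.loc[a4, config.tertile_by]
        rule = tertile_rule_from_reference(vals, name="A4-generation")
        cls.loc[a4] = np.asarray(rule.assign(vals).astype(str))
    return cls


def generate_longitudinal(
    baseline: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the long visit table and record ground truth.

    PACC value = baseline PACC + tertile trajectory + practice effect +
    random intercept + random slope x week + residual noise.  Functional
    measures follow analogous tertile-graded trends on the annual
    schedule; CDR-GS follows the discrete-time progression process.
    """
    if baseline.empty:
        raise ValueError("baseline table is empty")
    rng = _rng(config, 1)
    dp = config.decline_params
    hp = config.hazard_params

    cls = _tertile_class(baseline, config)
    chg240 = {
        "LEARN": dp.learn_change_240,
        "T1": dp.tertile_change_240[0],
        "T2": dp.tertile_change_240[1],
        "T3": dp.tertile_change_240[2],
    }
    cfi240 = {
        "LEARN": dp.cfi_learn_change_240,
        "T1": dp.cfi_tertile_change_240[0],
        "T2": dp.cfi_tertile_change_240[1],
        "T3": dp.cfi_tertile_change_240[2],
    }
    adl240 = {
        "LEARN": dp.adl_learn_change_240,
        "T1": dp.adl_tertile_change_240[0],
        "T2": dp.adl_tertile_change_240[1],
        "T3": dp.adl_tertile_change_240[2],
    }
    sb240 = {
        "LEARN": dp.cdrsb_learn_change_240,
        "T1": dp.cdrsb_tertile_change_240[0],
        "T2": dp.cdrsb_tertile_change_240[1],
        "T3": dp.cdrsb_tertile_change_240[2],
    }
    final = max(max(config.cognitive_weeks), max(config.functional_weeks))

    log_ptau = np.log(baseline["ptau217"].to_numpy(dtype=float))
    z = (log_ptau - log_ptau.mean()) / max(log_ptau.std(), 1e-12)
    hazard = 1.0 / (1.0 + np.exp(-(hp.intercept + hp.slope * z)))

    n = len(baseline)
    b0 = rng.normal(0.0, dp.random_intercept_sd, n) if dp.random_intercept_sd else np.zeros(n)
    b1 = rng.normal(0.0, dp.random_slope_sd, n) if dp.random_slope_sd else np.zeros(n)
    adl0 = np.clip(
        rng.normal(
            [config.demographic_params[a].adl_mean for a in baseline["arm"]],
            [config.demographic_params[a].adl_sd for a in baseline["arm"]],
        ),
        0, 45,
    )

    ptau_grad = dp.ptau_gradient_240 * np.maximum(
        baseline["ptau217"].to_numpy(dtype=float) - dp.ptau_ref, 0.0
    )

    records: list[dict] = []
    prog_week = np.full(n, np.nan)
    for i, (_, row) in enumerate(baseline.iterrows()):
        pid = row["id"]
        c = cls.iloc[i]
        shape = lambda w: (w / final) ** dp.shape_power if final > 0 else 0.0
        # cognitive schedule: PACC
        for k, w in enumerate(config.cognitive_weeks):
            value = (
                row["baseline_pacc"]
                + b0[i]
                + (chg240[c] + ptau_grad[i]) * shape(w)
                + dp.practice_gain(w, k)
                + b1[i] * w
                + (rng.normal(0.0, dp.residual_sd) if dp.residual_sd else 0.0)
            )
            records.append(
                {
                    "id": pid, "week": w, "measure": "PACC",
                    "value": float(value), "test_version": TEST_VERSIONS[k % 3],
                }
            )
        # progression process on the annual schedule
        progressed = False
        for w in config.functional_weeks:
            if w == 0:
                gs = 0.0
            else:
                if not progressed and rng.random() < hazard[i]:
                    progressed = True
                    prog_week[i] = w
                if progressed:
                    gs = 0.0 if (hp.reversion_prob and rng.random() < hp.reversion_prob) else 0.5
                else:
                    gs = 0.0
            noise = rng.normal(0.0, dp.functional_residual_sd, 3) if dp.functional_residual_sd else np.zeros(3)
            cfi = np.clip(row["baseline_cfi"] + cfi240[c] * shape(w) + noise[0], 0, 30)
            adl = np.clip(adl0[i] + adl240[c] * shape(w) + noise[1], 0, 45)
            sb = np.clip(
                sb240[c] * shape(w)
                + (hp.cdr_sb_progressed_boost if progressed else 0.0)
                + 0.3 * noise[2],
                0, 18,
            )
            sb = np.round(sb * 2.0) / 2.0
            records.append({"id": pid, "week": w, "measure": "CFI_combined",
                            "value": float(cfi), "test_version": None})
            records.append({"id": pid, "week": w, "measure": "ADL_partner",
                            "value": float(adl), "test_version": None})
            records.append({"id": pid, "week": w, "measure": "CDR_SB",
                            "value": float(sb), "test_version": None})
            records.append({"id": pid, "week": w, "measure": "CDR_GS",
                            "value": float(gs), "test_version": None})
    visits = pd.DataFrame(records)
    truth = GroundTruth(
        participants=pd.DataFrame(
            {
                "id": baseline["id"].to_numpy(),
                "tertile_class": cls.to_numpy(),
                "pacc_change_240": np.array([chg240[c] for c in cls]) + ptau_grad,
                "b0": b0,
                "b1": b1,
                "hazard": hazard,
                "progression_week": prog_week,
            }
        ),
        trajectory_coefficients=chg240,
        hazard_params=hp,
        config=config,
    )
    return visits, truth


def apply_missingness(visits: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Monotone MCAR dropout: per participant, a constant per-visit hazard
    over the distinct post-baseline scheduled weeks; once a visit is
    missed, all later records are removed.  Week 0 is always retained."""
    h = config.dropout_hazard
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"dropout_hazard must be in [0, 1], got {h}")
    if h == 0.0 or visits.empty:
        return visits.copy()
    rng = _rng(config, 2)
    weeks = np.sort(visits.loc[visits["week"] > 0, "week"].unique())
    ids = pd.unique(visits["id"])
    u = rng.random((len(ids), len(weeks)))
    miss = u < h
    # first missed post-baseline visit index, or len(weeks) if never
    first_miss = np.where(miss.any(axis=1), miss.argmax(axis=1), len(weeks))
    cutoff = pd.Series(
        [weeks[j] if j < len(weeks) else np.inf for j in first_miss], index=ids
    )
    keep = visits["week"] < cutoff.reindex(visits["id"]).to_numpy()
    return visits[keep].reset_index(drop=True)
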