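import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from adtraj.cohort import (
    BiomarkerArmParams,
    CohortConfig,
    DeclineParams,
    apply_missingness,
    generate_baseline,
    generate_longitudinal,
)


def quiet_decline(**overrides):
    params = dict(
        tertile_change_240=(0.0, 0.0, 0.0),
        learn_change_240=0.0,
        practice_effect=0.0,
        random_intercept_sd=0.0,
        random_slope_sd=0.0,
        residual_sd=0.0,
        functional_residual_sd=0.0,
    )
    params.update(overrides)
    return DeclineParams(**params)


class TestBaseline:
    def test_forced_counts(self):
        cfg = CohortConfig(n_learn=0, n_placebo=10, n_solanezumab=0, seed=1)
        b = generate_baseline(cfg)
        assert len(b) == 10 and (b["arm"] == "placebo").all()

    def test_determinism(self):
        cfg = CohortConfig(n_learn=15, n_placebo=15, n_solanezumab=15, seed=1)
        assert generate_baseline(cfg).equals(generate_baseline(cfg))

    def test_amyloid_ptau_correlation(self):
        """Configured transformed-scale correlation of 0.6 is recovered
        within +-0.05 at n=2000 (truncation off so moments are untouched)."""
        cfg = CohortConfig(
            n_learn=0, n_placebo=2000, n_solanezumab=0, seed=5, truncate_eligibility=False
        )
        b = generate_baseline(cfg)
        r = np.corrcoef(b["amyloid_cl"], np.log(b["ptau217"]))[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)

    def test_distributional_fidelity(self):
        """Sample biomarker moments within 3 SE of configured values when
        the eligibility truncation is inactive."""
        n = 4000
        cfg = CohortConfig(
            n_learn=0, n_placebo=n, n_solanezumab=0, seed=9, truncate_eligibility=False
        )
        bm = cfg.biomarker_params["placebo"]
        b = generate_baseline(cfg)
        se_mean = bm.amyloid_cl_sd / np.sqrt(n)
        assert abs(b["amyloid_cl"].mean() - bm.amyloid_cl_mean) < 3 * se_mean
        assert abs(b["amyloid_cl"].std() - bm.amyloid_cl_sd) < 3 * bm.amyloid_cl_sd / np.sqrt(2 * n)
        lp = np.log(b["ptau217"])
        assert abs(lp.mean() - bm.log_ptau_mean) < 3 * bm.log_ptau_sd / np.sqrt(n)

    def test_eligibility_truncation(self):
        cfg = CohortConfig(n_learn=200, n_placebo=200, n_solanezumab=0, seed=2)
        b = generate_baseline(cfg)
        learn = b[b["arm"] == "LEARN"]
        a4 = b[b["arm"] == "placebo"]
        assert (learn["amyloid_cl"] < cfg.eligibility_threshold_cl).all()
        assert (a4["amyloid_cl"] >= cfg.eligibility_threshold_cl).all()

    def test_tau_only_in_substudy(self):
        cfg = CohortConfig(n_learn=50, n_placebo=50, n_solanezumab=50, seed=3,
                           tau_substudy_fraction=0.4)
        b = generate_baseline(cfg)
        assert b.loc[~b["in_tau_substudy"], "tau_neocortical_suvr"].isna().all()
        assert b.loc[b["in_tau_substudy"], "tau_neocortical_suvr"].notna().all()
        assert not b.loc[b["arm"] == "LEARN", "in_tau_substudy"].any()

    def test_invalid_config_names_field(self):
        with pytest.raises(ValidationError, match="n_learn"):
            CohortConfig(n_learn=-1)
        with pytest.raises(ValidationError, match="amyloid_cl_sd"):
            BiomarkerArmParams(
                amyloid_cl_mean=60, amyloid_cl_sd=-1, log_ptau_mean=-1.4,
                log_ptau_sd=0.6, corr_amyloid_ptau=0.6,
            )
        with pytest.raises(ValidationError, match="corr_amyloid_ptau"):
            BiomarkerArmParams(
                amyloid_cl_mean=60, amyloid_cl_sd=30, log_ptau_mean=-1.4,
                log_ptau_sd=0.6, corr_amyloid_ptau=1.5,
            )
        with pytest.raises(ValidationError, match="schedule|week"):
            CohortConfig(cognitive_weeks=(24.0, 48.0))


class TestLongitudinal:
    def test_degenerate_generator_constant_pacc(self):
        cfg = CohortConfig(n_learn=5, n_placebo=5, n_solanezumab=5, seed=4,
                           decline_params=quiet_decline())
        b = generate_baseline(cfg)
        v, _ = generate_longitudinal(b, cfg)
        pacc = v[v["measure"] == "PACC"].merge(b[["id", "baseline_pacc"]], on="id")
        np.testing.assert_allclose(pacc["value"], pacc["baseline_pacc"], atol=1e-12)

    def test_practice_effect_by_construction(self):
        cfg = CohortConfig(
            n_learn=10, n_placebo=10, n_solanezumab=10, seed=4,
            decline_params=quiet_decline(practice_profile={24.0: 0.5}),
        )
        b = generate_baseline(cfg)
        v, _ = generate_longitudinal(b, cfg)
        pacc = v[v["measure"] == "PACC"]
        m24 = pacc.loc[pacc["week"] == 24, "value"].mean()
        m0 = pacc.loc[pacc["week"] == 0, "value"].mean()
        assert m24 - m0 == pytest.approx(0.5, abs=1e-12)

    def test_tertile_graded_decline(self):
        """Configured T3 week-240 change -1.5 vs T1 0.0 recovered within
        +-0.15 in empirical means at ~500/tertile."""
        cfg = CohortConfig(
            n_learn=0, n_placebo=1500, n_solanezumab=0, seed=6,
            decline_params=DeclineParams(
                tertile_change_240=(0.0, -0.7, -1.5), practice_effect=0.0,
                random_intercept_sd=0.0, random_slope_sd=0.0015, residual_sd=0.6,
            ),
        )
        b = generate_baseline(cfg)
        v, truth = generate_longitudinal(b, cfg)
        pacc = v[v["measure"] == "PACC"].pivot(index="id", columns="week", values="value")
        change = (pacc[240.0] - pacc[0.0]).rename("change")
        by = truth.participants.set_index("id")["tertile_class"]
        diff = change[by == "T3"].mean() - change[by == "T1"].mean()
        assert diff == pytest.approx(-1.5, abs=0.15)

    def test_test_version_cycles(self, small_cohort):
        _, _, visits, _ = small_cohort
        pacc = visits[visits["measure"] == "PACC"]
        week_to_version = pacc.groupby("week")["test_version"].unique()
        for k, (week, versions) in enumerate(week_to_version.sort_index().items()):
            assert list(versions) == ["ABC"[k % 3]]

    def test_schedule_conformity_and_ranges(self, small_cohort):
        cfg, _, visits, _ = small_cohort
        pacc_w = set(visits.loc[visits["measure"] == "PACC", "week"])
        assert pacc_w <= set(cfg.cognitive_weeks)
        func_w = set(visits.loc[visits["measure"] != "PACC", "week"])
        assert func_w <= set(cfg.functional_weeks)
        gs = visits.loc[visits["measure"] == "CDR_GS", "value"]
        assert gs.isin([0.0, 0.5, 1.0, 2.0, 3.0]).all()
        cfi = visits.loc[visits["measure"] == "CFI_combined", "value"]
        assert cfi.between(0, 30).all()
        adl = visits.loc[visits["measure"] == "ADL_partner", "value"]
        assert adl.between(0, 45).all()

    def test_unique_records(self, small_cohort):
        _, _, visits, _ = small_cohort
        assert not visits.duplicated(subset=["id", "week", "measure"]).any()

    def test_progression_hazard_increases_with_ptau(self):
        cfg = CohortConfig(n_learn=300, n_placebo=300, n_solanezumab=300, seed=8)
        b = generate_baseline(cfg)
        _, truth = generate_longitudinal(b, cfg)
        tp = truth.participants.merge(b[["id", "ptau217"]], on="id")
        hi = tp[tp["ptau217"] > tp["ptau217"].quantile(0.8)]["hazard"].mean()
        lo = tp[tp["ptau217"] < tp["ptau217"].quantile(0.2)]["hazard"].mean()
        assert hi > 2 * lo


class TestMissingness:
    def test_zero_hazard_identity(self, small_cohort):
        cfg, _, _, _ = small_cohort
        base = generate_baseline(cfg)
        v, _ = generate_longitudinal(base, cfg)
        cfg0 = cfg.model_copy(update={"dropout_hazard": 0.0})
        assert apply_missingness(v, cfg0).equals(v)

    def test_full_hazard_keeps_only_baseline(self, small_cohort):
        cfg, baseline, _, _ = small_cohort
        v, _ = generate_longitudinal(baseline, cfg)
        out = apply_missingness(v, cfg.model_copy(update={"dropout_hazard": 1.0}))
        assert (out["week"] == 0).all()
        assert set(out["id"]) == set(baseline["id"])

    def test_monotone_missingness(self, small_cohort):
        cfg, baseline, visits, _ = small_cohort
        full, _ = generate_longitudinal(baseline, cfg)
        sched = np.sort(full["week"].unique())
        for pid, g in visits.groupby("id"):
            present = np.sort(g["week"].unique())
            # observed weeks are a prefix of the schedule
            assert np.array_equal(present, sched[: len(present)])

    def test_retention_matches_binomial_expectation(self):
        cfg = CohortConfig(n_learn=0, n_placebo=1000, n_solanezumab=0, seed=12,
                           dropout_hazard=0.05)
        b = generate_baseline(cfg)
        v, _ = generate_longitudinal(b, cfg)
        out = apply_missingness(v, cfg)
        n_intervals = len(np.setdiff1d(v["week"].unique(), [0.0]))
        expected = 100 * 0.95**n_intervals
        retained = 100 * out.loc[out["week"] == 240, "id"].nunique() / 1000
        assert retained == pytest.approx(expected, abs=3.0)

    def test_bad_hazard_rejected(self):
        with pytest.raises(ValidationError, match="dropout_hazard"):
            CohortConfig(dropout_hazard=1.5)
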