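import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adtraj.commonality import (
    CommonalityError,
    all_subsets_r2,
    build_predictor_matrix,
    commonality_partition,
    predictor_pvalues,
    run_commonality,
    run_commonality_by_group,
)
from _oracles import all_subsets_r2_brute, commonality_by_linear_system


def random_instance(rng, n=80, p=4, collinear=False):
    X = rng.normal(size=(n, p))
    if collinear and p >= 2:
        X[:, 1] = X[:, 0] + 0.05 * rng.normal(size=n)
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(size=n)
    return y, X


class TestAllSubsetsR2:
    def test_matches_qr_oracle(self, rng):
        y, X = random_instance(rng, n=50, p=3)
        r2map = all_subsets_r2(y, X)
        brute = all_subsets_r2_brute(y, X)
        for mask in range(1, 8):
            assert r2map.get(mask) == pytest.approx(brute[mask], abs=1e-10)

    def test_orthogonal_additivity(self, rng):
        n, p = 90, 4
        raw = rng.normal(size=(n, p))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = Q @ rng.normal(size=p) + rng.normal(size=n)
        r2map = all_subsets_r2(y, Q)
        singles = [r2map.get(1 << i) for i in range(p)]
        for mask in range(1, 1 << p):
            total = sum(singles[i] for i in range(p) if mask >> i & 1)
            assert r2map.get(mask) == pytest.approx(total, abs=1e-8)

    def test_perfect_fit(self, rng):
        X = rng.normal(size=(40, 3))
        y = X[:, 0].copy()
        r2map = all_subsets_r2(y, X)
        for mask in range(1, 8):
            if mask & 1:
                assert r2map.get(mask) == pytest.approx(1.0, abs=1e-10)

    def test_monotone_in_subsets(self, rng):
        y, X = random_instance(rng, n=60, p=5)
        r2map = all_subsets_r2(y, X)
        for mask in range(1, 32):
            for i in range(5):
                if not mask >> i & 1:
                    assert r2map.get(mask | 1 << i) >= r2map.get(mask) - 1e-10

    def test_insufficient_n_rejected(self, rng):
        with pytest.raises(CommonalityError):
            all_subsets_r2(np.zeros(4), np.zeros((4, 4)))


class TestPartition:
    def test_single_predictor(self, rng):
        y, X = random_instance(rng, p=1)
        res = commonality_partition(all_subsets_r2(y, X))
        assert res.unique.iloc[0] == pytest.approx(res.r2_full, abs=1e-12)
        assert res.common.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_predictors_share_everything(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)  # marginal R² ~ 0.5
        X = np.column_stack([x, x])
        res = commonality_partition(all_subsets_r2(y, X))
        r2_single = all_subsets_r2(y, X).get(1)
        assert res.unique.iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert res.unique.iloc[1] == pytest.approx(0.0, abs=1e-10)
        assert res.coefficients[0b11] == pytest.approx(r2_single, abs=1e-10)
        assert sum(res.coefficients.values()) == pytest.approx(res.r2_full, abs=1e-10)

    def test_matches_linear_system_oracle(self, rng):
        for p in (2, 3, 4):
            y, X = random_instance(rng, n=70, p=p)
            r2map = all_subsets_r2(y, X)
            res = commonality_partition(r2map)
            oracle = commonality_by_linear_system(
                {m: r2map.get(m) for m in range(1, 1 << p)}, p
            )
            for mask in range(1, 1 << p):
                assert res.coefficients[mask] == pytest.approx(oracle[mask], abs=1e-10)

    def test_identities(self, rng):
        y, X = random_instance(rng, n=120, p=5, collinear=True)
        r2map = all_subsets_r2(y, X)
        res = commonality_partition(r2map)
        F = r2map.full_mask
        assert sum(res.coefficients.values()) == pytest.approx(res.r2_full, abs=1e-8)
        for i in range(5):
            assert res.coefficients[1 << i] == pytest.approx(
                r2map.get(F) - r2map.get(F & ~(1 << i)), abs=1e-10
            )
            marg = sum(c for m, c in res.coefficients.items() if m >> i & 1)
            assert marg == pytest.approx(r2map.get(1 << i), abs=1e-8)

    def test_suppressor_yields_negative_commonality_unclipped(self, rng):
        # classic suppressor: x2 unrelated to y but correlated with x1
        n = 4000
        x1 = rng.normal(size=n)
        x2 = x1 + rng.normal(size=n)
        y = x1 - x2 + 0.5 * rng.normal(size=n)
        res = commonality_partition(all_subsets_r2(y, np.column_stack([x1, x2])))
        assert res.coefficients[0b11] < 0
        assert sum(res.coefficients.values()) == pytest.approx(res.r2_full, abs=1e-10)

    def test_scale_invariance(self, rng):
        y, X = random_instance(rng, n=60, p=3)
        res1 = commonality_partition(all_subsets_r2(y, X))
        X2 = X * np.array([100.0, 0.01, 3.0])
        res2 = commonality_partition(all_subsets_r2(y, X2))
        for mask in range(1, 8):
            assert res1.coefficients[mask] == pytest.approx(res2.coefficients[mask], abs=1e-9)


class TestPvalues:
    def test_hand_computed_t(self):
        # n=5, single predictor: t = b / se(b), p from t(3)
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.3])
        p = predictor_pvalues(y, x.reshape(-1, 1))
        b = np.polyfit(x, y, 1)[0]
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        s2 = (resid**2).sum() / 3
        se = np.sqrt(s2 / ((x - x.mean()) ** 2).sum())
        expected = 2 * stats.t.sf(abs(b / se), df=3)
        assert p.iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_duplicated_pair_large_p_despite_marginal_signal(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = x + 0.5 * rng.normal(size=n)
        X = np.column_stack([x, x + 1e-8 * rng.normal(size=n)])
        p = predictor_pvalues(y, X)
        assert (p > 0.2).all()

    def test_null_pvalues_uniform(self, rng):
        """Under the null the full-model p-value for an independent
        predictor is uniform (KS not rejected at alpha=0.01)."""
        pvals = []
        for _ in range(400):
            y = rng.normal(size=40)
            X = rng.normal(size=(40, 2))
            pvals.append(predictor_pvalues(y, X).iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_marginal_mode(self, rng):
        y, X = random_instance(rng, n=50, p=2)
        p_full = predictor_pvalues(y, X, mode="full")
        p_marg = predictor_pvalues(y, X, mode="marginal")
        assert set(p_full.index) == set(p_marg.index)


class TestByGroup:
    def _cohortlike(self, rng, n=120, arm="placebo"):
        base = pd.DataFrame(
            {
                "id": [f"x{i:03d}" for i in range(n)],
                "arm": arm,
                "amyloid_cl": rng.normal(60, 30, n),
                "ptau217": rng.lognormal(-1.4, 0.5, n),
                "baseline_pacc": rng.normal(0, 2.7, n),
                "baseline_cfi": rng.integers(0, 10, n).astype(float),
                "age": rng.normal(72, 5, n),
                "apoe4_carrier": (rng.random(n) < 0.5).astype(float),
                "female": (rng.random(n) < 0.5).astype(float),
                "education": rng.normal(16, 3, n),
                "urg_member": (rng.random(n) < 0.1).astype(float),
            }
        )
        change = pd.DataFrame(
            {"id": base["id"], "change_240": -0.02 * base["amyloid_cl"] + rng.normal(0, 1, n)}
        )
        return base, change

    def test_single_group_reduces_to_partition(self, rng):
        base, change = self._cohortlike(rng)
        res = run_commonality_by_group({"placebo": change}, base, {"G": ("placebo",)})
        y, X = build_predictor_matrix(base, change)
        direct = run_commonality(y, X, group="G")
        assert res["G"].r2_full == pytest.approx(direct.r2_full, abs=1e-12)
        assert res["G"].unique.equals(direct.unique) or np.allclose(
            res["G"].unique, direct.unique
        )

    def test_treatment_only_when_arms_pooled(self, rng):
        b1, c1 = self._cohortlike(rng, arm="placebo")
        b2, c2 = self._cohortlike(rng, arm="solanezumab")
        b2["id"] = "y" + b2["id"].str[1:]
        c2["id"] = b2["id"]
        base = pd.concat([b1, b2], ignore_index=True)
        res = run_commonality_by_group(
            {"placebo": c1, "solanezumab": c2},
            base,
            {"pooled": ("placebo", "solanezumab"), "solo": ("placebo",)},
        )
        assert "treatment" in res["pooled"].names
        assert "treatment" not in res["solo"].names

    def test_small_group_skipped(self, rng):
        base, change = self._cohortlike(rng, n=10)
        res = run_commonality_by_group({"placebo": change}, base, {"G": ("placebo",)}, min_n=30)
        assert res == {}
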