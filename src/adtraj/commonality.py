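"""Commonality analysis: partitioning regression R² across predictors.

Given an outcome (participant-specific cognitive change score) and p
baseline predictors, commonality analysis fits an OLS model for every
non-empty predictor subset (2^p - 1 models) and decomposes the full-model
R² into 2^p - 1 *commonality coefficients* C(A), one per subset A: C({i})
is the variance explained uniquely by predictor i, and C(A) for |A| >= 2 is
the variance shared by exactly the predictors in A.

With F the full predictor set, the coefficients are obtained from the
all-subsets R² values by inclusion-exclusion:

    C(A) = - sum_{B subseteq A} (-1)^{|B|} R²(B ∪ (F \\ A))

which satisfies the conservation identity sum_A C(A) = R²(F), the unique
identity C({i}) = R²(F) - R²(F \\ {i}), and the marginal identity
sum_{A ∋ i} C(A) = R²({i}).  Coefficients can be negative in the presence
of suppressor predictors; they are reported as-is (truncation would break
conservation).

Subsets are represented as bitmasks over the predictor list; serialized
results are keyed by sorted predictor-name tuples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


class CommonalityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Predictor matrix assembly
# ---------------------------------------------------------------------------

#: The ten baseline predictors of cognitive change (treatment flag included
#: only where both randomized arms are pooled).
CORE_PREDICTORS = (
    "amyloid_cl",
    "ptau217",
    "baseline_pacc",
    "baseline_cfi",
    "age",
    "apoe4_carrier",
    "female",
    "education",
    "urg_member",
)
TREATMENT_PREDICTOR = "treatment"
TAU_PREDICTOR = "tau_neocortical_suvr"


def build_predictor_matrix(
    baseline: pd.DataFrame,
    change: pd.DataFrame,
    include_treatment: bool = False,
    include_tau: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Merge baseline predictors with change scores; listwise-delete
    incomplete cases (the deletion count is logged).

    ``change`` must have columns ``id`` and ``change_240``.  Returns
    ``(y, X)`` aligned on complete cases.
    """
    cols = list(CORE_PREDICTORS)
    if include_treatment:
        cols.append(TREATMENT_PREDICTOR)
    if include_tau:
        cols.append(TAU_PREDICTOR)
    base = baseline.set_index("id") if "id" in baseline.columns else baseline
    if TREATMENT_PREDICTOR in cols and TREATMENT_PREDICTOR not in base.columns:
        base = base.assign(treatment=(base["arm"] == "solanezumab").astype(float))
    missing_cols = [c for c in cols if c not in base.columns]
    if missing_cols:
        raise CommonalityError(f"baseline table lacks predictor columns {missing_cols}")
    merged = change.set_index("id").join(base[cols], how="inner")
    n0 = len(merged)
    merged = merged.dropna(subset=["change_240", *cols])
    if n0 - len(merged):
        logger.info("listwise deletion removed %d of %d participants", n0 - len(merged), n0)
    X = merged[cols].astype(float)
    return merged["change_240"].astype(float), X


# ---------------------------------------------------------------------------
# All-subsets R²
# ---------------------------------------------------------------------------


@dataclass
class SubsetR2Map:
    """R² for every non-empty predictor subset, keyed by bitmask."""

    names: tuple[str, ...]
    r2: dict[int, float]
    n: int
    rank_deficient: tuple[int, ...] = ()

    @property
    def p(self) -> int:
        return len(self.names)

    @property
    def full_mask(self) -> int:
        return (1 << self.p) - 1

    def get(self, mask: int) -> float:
        if mask == 0:
            return 0.0
        try:
            return self.r2[mask]
        except KeyError:
            raise CommonalityError(f"subset bitmask {mask} missing from R² map") from None

    def names_for(self, mask: int) -> tuple[str, ...]:
        return tuple(sorted(self.names[i] for i in range(self.p) if mask >> i & 1))


def _r2_of_subset(yc: np.ndarray, Xc: np.ndarray, sst: float) -> tuple[float, bool]:
    """R² of OLS on centered data (intercept profiled out by centering).

    Rank deficiency is handled by the minimum-norm least-squares solution
    (pseudoinverse); the flag is returned so callers can log it.
    """
    beta, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    r2 = 1.0 - float(resid @ resid) / sst
    return min(max(r2, 0.0), 1.0), rank < Xc.shape[1]


def all_subsets_r2(outcome, X) -> SubsetR2Map:
    """Compute R² for all 2^p - 1 non-empty predictor subsets.

    The intercept is always included (data are centered, which is
    equivalent).  Requires n > p + 1 for the full model.
    """
    Xdf = pd.DataFrame(X)
    names = tuple(str(c) for c in Xdf.columns)
    y = np.asarray(outcome, dtype=float)
    Xm = Xdf.to_numpy(dtype=float)
    n, p = Xm.shape
    if y.shape[0] != n:
        raise CommonalityError("outcome and predictor matrix lengths differ")
    if n <= p + 1:
        raise CommonalityError(f"need n > p + 1 (n={n}, p={p})")
    if not (np.isfinite(y).all() and np.isfinite(Xm).all()):
        raise CommonalityError("non-finite values in outcome or predictors; listwise-delete first")
    yc = y - y.mean()
    Xc = Xm - Xm.mean(axis=0)
    sst = float(yc @ yc)
    if sst == 0.0:
        raise CommonalityError("outcome has zero variance")
    idx = [np.flatnonzero([(m >> i) & 1 for i in range(p)]) for m in range(1 << p)]
    r2: dict[int, float] = {}
    deficient: list[int] = []
    for mask in range(1, 1 << p):
        val, bad = _r2_of_subset(yc, Xc[:, idx[mask]], sst)
        r2[mask] = val
        if bad:
            deficient.append(mask)
    if deficient:
        logger.info("%d subsets were rank-deficient; pseudoinverse used", len(deficient))
    return SubsetR2Map(names=names, r2=r2, n=n, rank_deficient=tuple(deficient))


# ---------------------------------------------------------------------------
# Commonality partition
# ---------------------------------------------------------------------------


@dataclass
class CommonalityResult:
    names: tuple[str, ...]
    coefficients: dict[int, float]  # C(A) keyed by bitmask
    r2_full: float
    n: int
    unique: pd.Series = field(default=None)  # type: ignore[assignment]
    common: pd.Series = field(default=None)  # type: ignore[assignment]
    total: pd.Series = field(default=None)  # type: ignore[assignment]
    pvalues: pd.Series | None = None
    group: str | None = None

    def coefficient_table(self) -> pd.DataFrame:
        p = len(self.names)
        rows = [
            {
                "subset": ",".join(sorted(self.names[i] for i in range(p) if m >> i & 1)),
                "size": bin(m).count("1"),
                "commonality": c,
            }
            for m, c in sorted(self.coefficients.items())
        ]
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "unique_r2": self.unique,
                "common_r2": self.common,
                "total_r2": self.total,
            }
        )
        if self.pvalues is not None:
            out["p_value"] = self.pvalues
        out["group"] = self.group
        out["n"] = self.n
        return out


def commonality_partition(r2map: SubsetR2Map) -> CommonalityResult:
    """Inclusion-exclusion commonality coefficients from an all-subsets map."""
    p = r2map.p
    F = r2map.full_mask
    coeffs: dict[int, float] = {}
    for A in range(1, 1 << p):
        comp = F & ~A
        # iterate all submasks B of A (including 0)
        total = -r2map.get(comp)  # B = 0 term: (-1)^0 * R²(comp)
        B = A
        while B:
            sign = -1.0 if bin(B).count("1") % 2 else 1.0
            total -= sign * r2map.get(B | comp)
            B = (B - 1) & A
        coeffs[A] = total
    unique = pd.Series(
        {r2map.names[i]: coeffs[1 << i] for i in range(p)}, name="unique_r2"
    )
    marginal = pd.Series({r2map.names[i]: r2map.get(1 << i) for i in range(p)})
    common = marginal - unique
    total = unique + common
    return CommonalityResult(
        names=r2map.names,
        coefficients=coeffs,
        r2_full=r2map.get(F),
        n=r2map.n,
        unique=unique,
        common=common.rename("common_r2"),
        total=total.rename("total_r2"),
    )


def predictor_pvalues(outcome, X, mode: str = "full") -> pd.Series:
    """Nominal two-sided p-value per predictor.

    ``mode='full'`` (default): t-tests on the full-model coefficients.
    ``mode='marginal'``: each predictor's slope test in its own
    single-predictor model.
    """
    Xdf = pd.DataFrame(X).astype(float)
    y = np.asarray(outcome, dtype=float)
    if mode == "full":
        fit = sm.OLS(y, sm.add_constant(Xdf)).fit()
        if fit.ssr <= 1e-12 * max(fit.centered_tss, 1.0):
            logger.warning("degenerate (perfect) fit; p-values reported as 0")
            return pd.Series(0.0, index=Xdf.columns, name="p_value")
        return fit.pvalues.drop("const").rename("p_value")
    if mode == "marginal":
        out = {}
        for c in Xdf.columns:
            fit = sm.OLS(y, sm.add_constant(Xdf[[c]])).fit()
            out[c] = float(fit.pvalues[c])
        return pd.Series(out, name="p_value")
    raise CommonalityError(f"unknown p-value mode {mode!r}")


def run_commonality(
    outcome, X, group: str | None = None, pvalue_mode: str = "full"
) -> CommonalityResult:
    """All-subsets R² -> commonality partition -> nominal p-values."""
    r2map = all_subsets_r2(outcome, X)
    res = commonality_partition(r2map)
    res.pvalues = predictor_pvalues(outcome, X, mode=pvalue_mode)
    res.group = group
    return res


def run_commonality_by_group(
    change_by_group: dict[str, pd.DataFrame],
    baseline: pd.DataFrame,
    groups: dict[str, tuple[str, ...]],
    include_tau: bool = False,
    min_n: int = 30,
    pvalue_mode: str = "full",
) -> dict[str, CommonalityResult]:
    """Run the partition per analysis group.

    ``groups`` maps an analysis label to the tuple of arms pooled into it,
    e.g. ``{"LEARN": ("LEARN",), "A4-combined": ("placebo", "solanezumab")}``.
    The treatment predictor is included only when both randomized arms are
    pooled ("where applicable").  Groups below ``min_n`` complete cases are
    skipped with a warning.
    """
    results: dict[str, CommonalityResult] = {}
    for label, arms in groups.items():
        missing = [a for a in arms if a not in change_by_group]
        if missing:
            raise CommonalityError(f"group {label!r}: no change scores for arms {missing}")
        change = pd.concat([change_by_group[a] for a in arms], ignore_index=True)
        arm_set = set(arms)
        include_treatment = {"placebo", "solanezumab"} <= arm_set
        base = baseline[baseline["arm"].isin(arm_set)]
        y, X = build_predictor_matrix(
            base, change, include_treatment=include_treatment, include_tau=include_tau
        )
        if len(y) < min_n:
            logger.warning("group %s skipped: n=%d below minimum %d", label, len(y), min_n)
            continue
        results[label] = run_commonality(y, X, group=label, pvalue_mode=pvalue_mode)
    return results
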