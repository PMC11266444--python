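"""Deterministic scoring rules for preclinical-AD cohort outcomes.

Covers the cognitive composite (PACC) z-sum, the combined Cognitive
Function Index, the linear SUVr -> Centiloid calibration for amyloid PET,
equal-frequency tertile assignment against a reference sample, and the
Mann-Whitney ROC AUC used to gauge how well plasma P-tau217 discriminates
elevated amyloid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class ScoringError(ValueError):
    pass


class DegenerateTertileError(ScoringError):
    pass


class UndefinedAUCError(ScoringError):
    pass


# ---------------------------------------------------------------------------
# PACC composite
# ---------------------------------------------------------------------------

#: (name, (low, high)) for the four PACC components:
#: FCSRT free + total recall, Logical Memory delayed recall,
#: Digit-Symbol substitution, MMSE.
PACC_COMPONENTS = (
    ("fcsrt", (0.0, 96.0)),
    ("logical_memory", (0.0, 25.0)),
    ("digit_symbol", (0.0, 93.0)),
    ("mmse", (0.0, 30.0)),
)


@dataclass(frozen=True)
class BaselineNorms:
    """Baseline means/SDs used to z-score each PACC component."""

    means: tuple[float, float, float, float]
    sds: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.means) != 4 or len(self.sds) != 4:
            raise ScoringError("norms require exactly four components")
        if any(s <= 0 for s in self.sds):
            raise ScoringError("component SDs must be positive")


def compute_pacc(component_scores, norms: BaselineNorms, ranges=PACC_COMPONENTS):
    """Sum of four component z-scores; negative = worse cognition.

    ``component_scores`` is a length-4 sequence ordered as
    :data:`PACC_COMPONENTS`.  A missing (NaN/None) component yields a
    missing composite (``nan``) — no prorating.  An out-of-range component
    raises :class:`ScoringError`.
    """
    x = np.asarray([np.nan if v is None else float(v) for v in component_scores])
    if x.shape != (4,):
        raise ScoringError(f"expected 4 component scores, got shape {x.shape}")
    for v, (name, (lo, hi)) in zip(x, ranges):
        if np.isfinite(v) and not (lo <= v <= hi):
            raise ScoringError(f"component {name!r}={v} outside its range [{lo}, {hi}]")
    if np.isnan(x).any():
        return float("nan")
    mu = np.asarray(norms.means)
    sd = np.asarray(norms.sds)
    return float(np.sum((x - mu) / sd))


def combine_cfi(participant_score: float, partner_score: float) -> float:
    """Combined Cognitive Function Index: participant + study-partner totals,
    each 0-15, summed to 0-30."""
    for label, v in (("participant", participant_score), ("partner", partner_score)):
        if not (0 <= v <= 15):
            raise ScoringError(f"CFI {label} score {v} outside [0, 15]")
    return float(participant_score + partner_score)


# ---------------------------------------------------------------------------
# Centiloid calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CentiloidCalibration:
    """Affine map from tracer SUVr (cerebellar reference) to Centiloids."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ScoringError("Centiloid calibration slope must be positive")

    @classmethod
    def from_anchors(cls, p1: tuple[float, float], p2: tuple[float, float]) -> "CentiloidCalibration":
        (x1, y1), (x2, y2) = p1, p2
        slope = (y2 - y1) / (x2 - x1)
        return cls(slope=slope, intercept=y1 - slope * x1)


#: Default calibration through the two printed anchors: the elevation
#: cutpoint (SUVr 1.15 = 33 CL) and the elevated-cohort mean (1.30 = 66.2 CL).
DEFAULT_CENTILOID = CentiloidCalibration.from_anchors((1.15, 33.0), (1.30, 66.2))


def suvr_to_centiloid(suvr, cal: CentiloidCalibration = DEFAULT_CENTILOID):
    """Convert SUVr to the standard Centiloid scale (vectorized)."""
    s = np.asarray(suvr, dtype=float)
    if np.any(s <= 0):
        raise ScoringError("SUVr must be positive")
    out = cal.slope * s + cal.intercept
    return float(out) if np.isscalar(suvr) else out


def centiloid_to_suvr(cl, cal: CentiloidCalibration = DEFAULT_CENTILOID):
    """Exact inverse of :func:`suvr_to_centiloid`."""
    c = np.asarray(cl, dtype=float)
    out = (c - cal.intercept) / cal.slope
    return float(out) if np.isscalar(cl) else out


# ---------------------------------------------------------------------------
# Tertiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TertileRule:
    """Two cutpoints splitting a biomarker into T1/T2/T3.

    Boundary convention: half-open — T1 = (-inf, lower), T2 = [lower, upper),
    T3 = [upper, inf).
    """

    lower: float
    upper: float
    reference: str = "analysis-sample"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise DegenerateTertileError(
                f"tertile cutpoints must be increasing, got ({self.lower}, {self.upper})"
            )

    def assign(self, values) -> pd.Categorical:
        v = np.asarray(values, dtype=float)
        labels = np.where(v < self.lower, "T1", np.where(v < self.upper, "T2", "T3"))
        labels = np.where(np.isnan(v), None, labels)
        return pd.Categorical(labels, categories=["T1", "T2", "T3"], ordered=True)


def tertile_rule_from_reference(reference_values, name: str = "analysis-sample") -> TertileRule:
    """Cutpoints at the 1/3 and 2/3 quantiles (linear interpolation) of the
    reference sample."""
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < 3:
        raise ScoringError("reference sample needs at least 3 finite values")
    q1, q2 = np.quantile(ref, [1 / 3, 2 / 3])
    if not q1 < q2:
        raise DegenerateTertileError(f"degenerate tertiles: quantiles ({q1}, {q2}) coincide")
    return TertileRule(lower=float(q1), upper=float(q2), reference=name)


def assign_tertiles(values, rule: TertileRule | None = None, reference=None):
    """Assign T1/T2/T3 labels; returns ``(labels, rule)``.

    Either an explicit :class:`TertileRule` or a reference sample (from
    which cutpoints are computed) must be given.
    """
    if rule is None:
        if reference is None:
            raise ScoringError("provide a TertileRule or a reference sample")
        rule = tertile_rule_from_reference(reference)
    return rule.assign(values), rule


# ---------------------------------------------------------------------------
# ROC AUC
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_positive > score_negative) + 1/2 P(tie).

    Computed from midranks, which is algebraically identical to averaging
    pairwise concordance over all positive x negative pairs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ScoringError("scores and labels must be 1-D and aligned")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # midranks handle ties
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
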