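"""CDR-GS progression endpoint and Kaplan-Meier estimation.

Progression to functional impairment is defined as two consecutive global
CDR ratings above 0, or a rating above 0 at the end-of-study assessment.
The event is dated at the confirming (second) rating; participants never
meeting the definition are right-censored at their last attended CDR
visit.  Curves are estimated with the product-limit (Kaplan-Meier)
estimator with Greenwood variance and, by default, complementary log-log
95% confidence intervals (bounded in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


class ProgressionError(ValueError):
    pass


VALID_CDR_GS = (0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class ProgressionOutcome:
    id: object
    event: bool
    time_weeks: float


def derive_progression(
    weeks,
    ratings,
    final_week: float,
    participant_id=None,
    consecutive_attended: bool = True,
    event_at_confirmation: bool = True,
    endpoint_requires_final_scheduled: bool = True,
) -> ProgressionOutcome:
    """Classify one participant's CDR-GS series as event or censored.

    Parameters
    ----------
    weeks, ratings
        The attended CDR visits in increasing week order; week 0 with
        rating 0 must be present (the cohort is unimpaired at baseline).
    final_week
        The scheduled end-of-study week for the endpoint rule.
    consecutive_attended
        If True (default), "consecutive" means consecutive *attended*
        assessments — an intervening missed visit does not reset the pair.
        If False, the two elevated ratings must be at adjacent scheduled
        weeks.
    event_at_confirmation
        Date the event at the second of the pair (default) or at the first.
    endpoint_requires_final_scheduled
        If True (default), the single-elevated-endpoint rule fires only
        when the elevated rating occurs at ``final_week`` itself; if False,
        an elevated rating at a dropout's last attended visit also counts.
    """
    w = np.asarray(weeks, dtype=float)
    r = np.asarray(ratings, dtype=float)
    if w.size == 0 or w.size != r.size:
        raise ProgressionError("series must be non-empty and aligned")
    if np.any(np.diff(w) <= 0):
        raise ProgressionError("weeks must be strictly increasing")
    bad = ~np.isin(r, VALID_CDR_GS)
    if bad.any():
        raise ProgressionError(f"invalid CDR-GS value(s) {sorted(set(r[bad]))}")
    if w[0] != 0:
        raise ProgressionError("series must start at week 0")
    if r[0] > 0:
        raise ProgressionError("baseline CDR-GS > 0 violates eligibility (unimpaired at entry)")

    # two-consecutive rule: first pair of adjacent attended elevated ratings
    schedule_gap = np.median(np.diff(w)) if w.size > 1 else None
    for i in range(w.size - 1):
        if r[i] > 0 and r[i + 1] > 0:
            if not consecutive_attended and schedule_gap is not None:
                if not np.isclose(w[i + 1] - w[i], schedule_gap):
                    continue
            t = w[i + 1] if event_at_confirmation else w[i]
            return ProgressionOutcome(participant_id, True, float(t))
    # endpoint rule: elevated rating at the last assessment
    if r[-1] > 0:
        if (not endpoint_requires_final_scheduled) or w[-1] >= final_week:
            return ProgressionOutcome(participant_id, True, float(w[-1]))
    return ProgressionOutcome(participant_id, False, float(w[-1]))


def derive_progression_table(
    cdr: pd.DataFrame, final_week: float, **rule_flags
) -> pd.DataFrame:
    """Vectorize :func:`derive_progression` over a long table with columns
    ``id, week, value`` (CDR-GS)."""
    rows = []
    for pid, g in cdr.sort_values("week").groupby("id", sort=False):
        out = derive_progression(
            g["week"].to_numpy(), g["value"].to_numpy(), final_week,
            participant_id=pid, **rule_flags,
        )
        rows.append({"id": pid, "event": out.event, "time_weeks": out.time_weeks})
    return pd.DataFrame(rows)


@dataclass
class KMCurve:
    """Product-limit curve on the distinct event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    label: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.label,
                "time": self.times,
                "survival": self.survival,
                "lo": self.ci_lower,
                "hi": self.ci_upper,
                "at_risk": self.at_risk,
            }
        )

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def kaplan_meier(outcomes: pd.DataFrame, label: str | None = None, ci: str = "loglog") -> KMCurve:
    """Kaplan-Meier fit of a ``(id, event, time_weeks)`` outcome table.

    ``ci='loglog'`` (default) uses the complementary log-log (exponential
    Greenwood) interval; ``ci='linear'`` the plain Greenwood interval
    clipped to [0, 1].
    """
    if len(outcomes) == 0:
        raise ProgressionError("empty outcome table")
    durations = outcomes["time_weeks"].to_numpy(dtype=float)
    events = outcomes["event"].to_numpy(dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events, label=label or "KM")
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    if ci == "loglog":
        ci_df = kmf.confidence_interval_  # lifelines default is log-log
        lo = ci_df.iloc[:, 0].to_numpy(dtype=float)
        hi = ci_df.iloc[:, 1].to_numpy(dtype=float)
    elif ci == "linear":
        # Greenwood variance from lifelines, symmetric interval clipped to [0,1]
        var = (kmf.survival_function_.iloc[:, 0] ** 2).to_numpy() * np.asarray(
            _greenwood_cumsum(durations, events, grid)
        )
        se = np.sqrt(var)
        lo = np.clip(surv - 1.96 * se, 0.0, 1.0)
        hi = np.clip(surv + 1.96 * se, 0.0, 1.0)
    else:
        raise ProgressionError(f"unknown ci type {ci!r}")
    at_risk = np.array([int((durations >= t).sum()) for t in grid])
    return KMCurve(grid, surv, lo, hi, at_risk, label=label)


def _greenwood_cumsum(durations, events, grid):
    """Cumulative sum d/(n(n-d)) over event times up to each grid point."""
    out = []
    acc = 0.0
    for t in grid:
        d = int(((durations == t) & events).sum())
        n = int((durations >= t).sum())
        if d and n > d:
            acc += d / (n * (n - d))
        elif d and n == d:
            acc = np.inf
        out.append(acc)
    return out


def progression_by_tertile(
    outcomes: pd.DataFrame, tertiles: pd.Series, final_week: float, ci: str = "loglog"
) -> tuple[dict[str, KMCurve], pd.Series]:
    """One KM curve per tertile stratum plus cumulative incidence
    (1 - S) at ``final_week`` per stratum.

    ``tertiles`` is indexed by participant id and must cover every id in
    ``outcomes``; empty strata are omitted with a warning.
    """
    missing = set(outcomes["id"]) - set(tertiles.index)
    if missing:
        raise ProgressionError(f"tertile labels missing for {len(missing)} participants")
    curves: dict[str, KMCurve] = {}
    incidence = {}
    labeled = outcomes.assign(stratum=tertiles.reindex(outcomes["id"]).to_numpy())
    for stratum in pd.unique(labeled["stratum"].dropna()):
        sub = labeled[labeled["stratum"] == stratum]
        if len(sub) == 0:
            continue
        curve = kaplan_meier(sub, label=str(stratum), ci=ci)
        curves[str(stratum)] = curve
        incidence[str(stratum)] = 1.0 - curve.survival_at(final_week)
    return curves, pd.Series(incidence, name="cumulative_incidence").sort_index()
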