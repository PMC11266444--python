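"""Participant-specific cognitive change scores from random-slope models.

Step one of the two-step variance-explained procedure: within each cohort
(placebo, active, observational) fit a linear mixed-effects model of the
outcome with fixed effects for test version and two natural-cubic-spline
terms for time, plus participant-specific random intercepts and slopes:

    y_ij = alpha + version effects + f(t_ij) + b0_i + b1_i t_ij + e_ij.

Each participant's estimated change from baseline at week 240 is then

    change_i = [f(240) - f(0)] + b1_i * 240,

the individual empirical-Bayes (BLUP) predicted trajectory difference with
the test version held fixed (version effects cancel in the difference by
construction).  Time enters the random slope in units of 100 weeks
internally for conditioning; change scores are reported in outcome units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .splines import SplineSpec, natural_spline_basis

logger = logging.getLogger(__name__)

TIME_SCALE = 100.0  # weeks per internal time unit


class ChangeScoreError(ValueError):
    pass


@dataclass
class RandomSlopeFit:
    group: str
    fixed_effects: pd.Series
    cov_re: np.ndarray  # 2x2 intercept/slope covariance (slope per 100 weeks)
    residual_sd: float
    blups: pd.DataFrame  # index id; columns intercept, slope (per week)
    loglik: float
    spline: SplineSpec
    version_levels: tuple[str, ...]
    converged: bool
    boundary: bool  # near-singular random-effect covariance

    def fixed_time_effect(self, week: float) -> float:
        """Fixed-effect mean time trend at ``week`` relative to week 0,
        test version held at the reference level."""
        basis = natural_spline_basis([week, 0.0], self.spline)
        diff = basis[0] - basis[1]
        coefs = np.array([self.fixed_effects[f"ns{j + 1}"] for j in range(self.spline.df)])
        return float(diff @ coefs)


def fit_random_slope_model(
    visits: pd.DataFrame,
    group: str | None = None,
    spline: SplineSpec | None = None,
    outcome: str = "PACC",
) -> RandomSlopeFit:
    """ML fit of the per-group random-intercept/slope model.

    ``visits`` is the long table (id, week, measure, value, test_version);
    if ``group`` is given, the table must already be restricted to that
    group's participants.
    """
    df = visits[visits["measure"] == outcome] if "measure" in visits.columns else visits
    df = df.dropna(subset=["value"]).copy()
    if df.empty:
        raise ChangeScoreError(f"no records for outcome {outcome!r}")
    counts = df.groupby("id")["week"].nunique()
    if (counts >= 2).sum() < 2:
        raise ChangeScoreError("need at least 2 participants with at least 2 visits")

    weeks = np.sort(df["week"].unique()).astype(float)
    spline = spline or SplineSpec.from_weeks(weeks)
    basis = natural_spline_basis(df["week"].to_numpy(dtype=float), spline)

    exog = pd.DataFrame({"const": 1.0}, index=df.index)
    if "test_version" in df.columns:
        versions = tuple(sorted(df["test_version"].dropna().astype(str).unique()))
        for v in versions[1:]:
            exog[f"version[{v}]"] = (df["test_version"].astype(str) == v).astype(float)
    else:
        versions = ()
    for j in range(basis.shape[1]):
        exog[f"ns{j + 1}"] = basis[:, j]

    t_scaled = df["week"].to_numpy(dtype=float) / TIME_SCALE
    exog_re = np.column_stack((np.ones(len(df)), t_scaled))

    model = MixedLM(
        df["value"].to_numpy(dtype=float),
        exog.to_numpy(),
        groups=df["id"].to_numpy(),
        exog_re=exog_re,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method=["lbfgs", "powell"], maxiter=500)
    cov_re = np.asarray(fit.cov_re)  # already on the outcome scale
    eigs = np.linalg.eigvalsh(cov_re)
    boundary = bool(eigs.min() < 1e-8 * max(eigs.max(), 1.0))
    if boundary:
        logger.warning("random-effect covariance near singular (boundary fit)")

    # empirical BLUPs b_i = G Z_i' (Z_i G Z_i' + s2 I)^-1 (y_i - X_i beta),
    # computed directly: well conditioned even as the residual variance
    # approaches zero (exact-fit limit -> per-participant least squares)
    beta = np.asarray(fit.fe_params)
    resid_all = df["value"].to_numpy(dtype=float) - exog.to_numpy() @ beta
    gids = df["id"].to_numpy()
    ids, inv = np.unique(gids, return_inverse=True)
    b = np.empty((ids.size, 2))
    for k in range(ids.size):
        m = inv == k
        Zi = exog_re[m]
        Vi = Zi @ cov_re @ Zi.T + fit.scale * np.eye(int(m.sum()))
        b[k] = cov_re @ Zi.T @ np.linalg.solve(Vi, resid_all[m])
    blups = pd.DataFrame(
        {"intercept": b[:, 0], "slope": b[:, 1] / TIME_SCALE}, index=pd.Index(ids, name="id")
    )
    names = list(exog.columns)
    return RandomSlopeFit(
        group=group or "all",
        fixed_effects=pd.Series(np.asarray(fit.fe_params), index=names),
        cov_re=cov_re,
        residual_sd=float(np.sqrt(fit.scale)),
        blups=blups,
        loglik=float(fit.llf),
        spline=spline,
        version_levels=versions,
        converged=bool(fit.converged),
        boundary=boundary,
    )


def estimate_change(
    fit: RandomSlopeFit,
    at_week: float = 240.0,
    visits: pd.DataFrame | None = None,
    at_observed: bool = False,
) -> pd.DataFrame:
    """Participant-specific estimated change from baseline at ``at_week``.

    Default: BLUP-based individual prediction, ``fixed(at_week) - fixed(0)
    + b1_i * at_week``.  With ``at_observed=True`` the change is evaluated
    at each participant's last observed week instead (requires ``visits``),
    for sensitivity to missing end-of-study assessments.
    """
    if at_observed:
        if visits is None:
            raise ChangeScoreError("at_observed=True requires the visit table")
        last = visits.dropna(subset=["value"]).groupby("id")["week"].max()
        rows = []
        for pid, b1 in fit.blups["slope"].items():
            w = float(last.get(pid, at_week))
            rows.append({"id": pid, "change_240": fit.fixed_time_effect(w) + b1 * w})
        return pd.DataFrame(rows)
    fixed_change = fit.fixed_time_effect(at_week)
    out = pd.DataFrame(
        {
            "id": fit.blups.index,
            "change_240": fixed_change + fit.blups["slope"].to_numpy() * at_week,
        }
    )
    return out.reset_index(drop=True)


def change_scores_by_group(
    visits: pd.DataFrame,
    baseline: pd.DataFrame,
    spline: SplineSpec | None = None,
    outcome: str = "PACC",
    at_week: float = 240.0,
) -> tuple[dict[str, pd.DataFrame], dict[str, RandomSlopeFit]]:
    """Fit the random-slope model separately per arm and derive change
    scores; returns ``(change tables, fits)`` keyed by arm."""
    arms = baseline.set_index("id")["arm"] if "id" in baseline.columns else baseline["arm"]
    changes: dict[str, pd.DataFrame] = {}
    fits: dict[str, RandomSlopeFit] = {}
    for arm in pd.unique(arms):
        ids = arms.index[arms == arm]
        sub = visits[visits["id"].isin(ids)]
        fit = fit_random_slope_model(sub, group=str(arm), spline=spline, outcome=outcome)
        fits[str(arm)] = fit
        changes[str(arm)] = estimate_change(fit, at_week=at_week)
    return changes, fits
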