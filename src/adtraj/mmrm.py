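"""Mixed model for repeated measures (MMRM) with heterogeneous Toeplitz
covariance.

The marginal model for an outcome observed on a common visit schedule
(weeks w_1 .. w_T) is

    y_i ~ N(X_i beta, Sigma[obs_i, obs_i]),    Sigma = D R D,

with D = diag(sigma_1 .. sigma_T) (a free SD per scheduled visit — the
"heterogeneous" part) and R a Toeplitz correlation matrix, R[s, t] =
rho_{|s-t|}, rho_0 = 1: correlations depend only on visit *lag*.  The mean
includes a per-group intercept, per-group natural-cubic-spline terms for
time, and baseline covariates.  Estimation is by maximum likelihood with
beta profiled out (GLS), optimizing over log sigma_t and the Toeplitz
correlation parameters.

The lag correlations are parameterized through partial autocorrelations
mapped by tanh: any point of the unconstrained search space maps to a
positive-definite Toeplitz correlation matrix (Durbin-Levinson recursion),
so the optimizer can never leave the PD cone.

Participants with incomplete schedules contribute the sub-matrix of Sigma
at their observed visits; computation groups participants by missingness
pattern so each pattern costs one Cholesky factorization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular, toeplitz
from scipy.optimize import minimize

from .splines import SplineSpec, natural_spline_basis

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))


class MmrmError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimizer fails outright; carries the
    optimizer trace in ``.trace``."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Toeplitz correlation via partial autocorrelations
# ---------------------------------------------------------------------------


def pacf_to_acf(phi) -> np.ndarray:
    """Map partial autocorrelations phi_1..phi_m in (-1,1) to lag
    correlations rho_1..rho_m of a stationary process (Durbin-Levinson).

    Every PD Toeplitz correlation matrix corresponds to exactly one such
    phi, and every phi in (-1,1)^m yields a PD matrix.
    """
    phi = np.asarray(phi, dtype=float)
    m = phi.size
    rho = np.zeros(m)
    if m == 0:
        return rho
    a = np.zeros(m)  # AR coefficients of increasing order
    a[0] = phi[0]
    rho[0] = phi[0]
    for k in range(1, m):
        rho[k] = a[:k] @ rho[:k][::-1] + phi[k] * (1.0 - a[:k] @ rho[:k])
        a[:k] = a[:k] - phi[k] * a[:k][::-1]
        a[k] = phi[k]
    return rho


def toeplitz_correlation(phi) -> np.ndarray:
    rho = pacf_to_acf(phi)
    return toeplitz(np.concatenate(([1.0], rho)))


# ---------------------------------------------------------------------------
# Model specification and fit container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MmrmSpec:
    """Specification for one outcome's trajectory model.

    ``grouping`` names a baseline column whose levels get separate
    intercepts and spline-time curves (e.g. cohort x biomarker tertile);
    ``covariates`` are baseline columns entering as main effects
    (continuous ones are centered at their sample mean).
    """

    outcome: str = "PACC"
    grouping: str = "group"
    covariates: tuple[str, ...] = ("age", "education", "apoe4_carrier")
    spline: SplineSpec | None = None
    covariance: str = "toeplitz_h"  # or "independence"
    reml: bool = False

    def __post_init__(self):
        if self.covariance not in ("toeplitz_h", "independence"):
            raise MmrmError(f"unknown covariance structure {self.covariance!r}")


@dataclass
class MmrmFit:
    spec: MmrmSpec
    beta: pd.Series
    vcov: pd.DataFrame
    sigma: np.ndarray  # per scheduled visit
    rho: np.ndarray  # lag correlations
    pacf: np.ndarray
    loglik: float
    visit_weeks: np.ndarray
    group_levels: tuple[str, ...]
    covariate_profile: pd.Series
    n_obs: int
    n_participants: int
    converged: bool
    n_iter: int
    message: str = ""

    @property
    def covariance_matrix(self) -> np.ndarray:
        D = np.diag(self.sigma)
        R = toeplitz(np.concatenate(([1.0], self.rho)))
        return D @ R @ D

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "covariance": self.spec.covariance,
            "beta": self.beta.to_dict(),
            "sigma": self.sigma.tolist(),
            "rho": self.rho.tolist(),
            "loglik": self.loglik,
            "visit_weeks": self.visit_weeks.tolist(),
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "converged": bool(self.converged),
        }


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------


def build_design(
    visits: pd.DataFrame, baseline: pd.DataFrame, spec: MmrmSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], dict]:
    """Assemble (X, y, participant index, visit index) for the MMRM.

    Off-schedule weeks are snapped to the nearest scheduled week with a
    logged warning (the Toeplitz lag structure requires a common grid).
    """
    df = visits[visits["measure"] == spec.outcome] if "measure" in visits.columns else visits
    if df.empty:
        raise MmrmError(f"no visit records for outcome {spec.outcome!r}")
    base = baseline.set_index("id") if "id" in baseline.columns else baseline
    need = [spec.grouping, *spec.covariates]
    missing = [c for c in need if c not in base.columns]
    if missing:
        raise MmrmError(f"baseline table lacks columns {missing}")
    df = df.join(base[need], on="id", how="inner").dropna(subset=["value", *need])
    # canonical row order: estimates are then invariant (bit-for-bit) to
    # the order participants arrive in
    df = df.sort_values(["id", "week"], kind="mergesort").reset_index(drop=True)

    weeks = np.sort(df["week"].unique()).astype(float)
    obs_w = df["week"].to_numpy(dtype=float)
    snapped = weeks[np.abs(obs_w[:, None] - weeks[None, :]).argmin(axis=1)]
    if not np.array_equal(snapped, obs_w):
        logger.warning("off-schedule visit weeks snapped to nearest scheduled week")
    visit_idx = np.searchsorted(weeks, snapped)

    spline = spec.spline or SplineSpec.from_weeks(weeks)
    basis = natural_spline_basis(snapped, spline)

    levels = tuple(sorted(str(l) for l in pd.unique(base[spec.grouping].dropna())))
    grp = df[spec.grouping].astype(str).to_numpy()
    cols: list[np.ndarray] = []
    names: list[str] = []
    for lev in levels:
        ind = (grp == lev).astype(float)
        cols.append(ind)
        names.append(f"{spec.grouping}[{lev}]")
        for j in range(basis.shape[1]):
            cols.append(ind * basis[:, j])
            names.append(f"{spec.grouping}[{lev}]:ns{j + 1}")
    profile = {}
    for c in spec.covariates:
        v = df[c].to_numpy(dtype=float)
        mean = float(np.mean(v))
        cols.append(v - mean)
        names.append(c)
        profile[c] = mean
    X = np.column_stack(cols)
    y = df["value"].to_numpy(dtype=float)
    ids, pidx = np.unique(df["id"].to_numpy(), return_inverse=True)
    meta = {
        "weeks": weeks,
        "spline": spline,
        "levels": levels,
        "profile": pd.Series(profile),
        "ids": ids,
    }
    return X, y, pidx, visit_idx, names, meta


# ---------------------------------------------------------------------------
# Profiled likelihood machinery
# ---------------------------------------------------------------------------


class _PatternData:
    """Observations regrouped by missingness pattern for fast likelihood."""

    def __init__(self, X, y, pidx, vidx, T):
        self.T = T
        self.q = X.shape[1]
        order = np.lexsort((vidx, pidx))
        X, y, pidx, vidx = X[order], y[order], pidx[order], vidx[order]
        patterns: dict[tuple, list[int]] = {}
        bounds = np.flatnonzero(np.diff(pidx)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(pidx)]))
        for s, e in zip(starts, ends):
            key = tuple(vidx[s:e])
            if len(set(key)) != len(key):
                raise MmrmError("duplicate (participant, visit) records")
            patterns.setdefault(key, []).append((s, e))
        self.blocks = []
        for key, spans in patterns.items():
            t_p = len(key)
            n_p = len(spans)
            Yp = np.empty((n_p, t_p))
            Xp = np.empty((n_p, t_p, self.q))
            for r, (s, e) in enumerate(spans):
                Yp[r] = y[s:e]
                Xp[r] = X[s:e]
            self.blocks.append((np.asarray(key, dtype=int), Yp, Xp))
        self.n_obs = len(y)
        self.n_participants = len(starts)

    def profile_nll(self, Sigma, reml=False, want_beta=False):
        """Negative log-likelihood with beta profiled out by GLS."""
        q = self.q
        A = np.zeros((q, q))
        b = np.zeros(q)
        yty = 0.0
        logdet = 0.0
        cache = []
        for idx, Yp, Xp in self.blocks:
            Sp = Sigma[np.ix_(idx, idx)]
            L = cholesky(Sp, lower=True)
            logdet += Yp.shape[0] * 2.0 * np.log(np.diag(L)).sum()
            t_p, n_p = idx.size, Yp.shape[0]
            Wy = solve_triangular(L, Yp.T, lower=True)  # (t_p, n_p)
            WX = solve_triangular(
                L, Xp.transpose(1, 0, 2).reshape(t_p, n_p * q), lower=True
            ).reshape(t_p, n_p, q)
            A += np.einsum("tnq,tnr->qr", WX, WX)
            b += np.einsum("tnq,tn->q", WX, Wy)
            yty += float((Wy**2).sum())
            if want_beta:
                cache.append((Wy, WX))
        # lstsq handles rank deficiency (e.g. a time basis that is
        # identically zero when only one visit is observed) via the
        # minimum-norm solution
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        if want_beta:
            # accurate residual quadratic form: the yty - b'beta shortcut
            # cancels catastrophically when the signal dominates the noise
            rss = sum(
                float(((Wy - np.einsum("tnq,q->tn", WX, beta)) ** 2).sum())
                for Wy, WX in cache
            )
        else:
            rss = yty - float(b @ beta)
        nll = 0.5 * (self.n_obs * LOG2PI + logdet + rss)
        if reml:
            sign, ld = np.linalg.slogdet(A)
            nll += 0.5 * ld - 0.5 * q * LOG2PI
        if want_beta:
            return nll, beta, np.linalg.pinv(A)
        return nll


def _theta_to_sigma_matrix(theta, T, structure):
    sig = np.exp(theta[:T])
    if structure == "toeplitz_h":
        phi = np.tanh(theta[T:])
        R = toeplitz_correlation(phi)
    else:
        phi = np.zeros(0)
        R = np.eye(T)
    Sigma = (sig[:, None] * R) * sig[None, :]
    return Sigma, sig, pacf_to_acf(phi) if phi.size else np.zeros(T - 1)


def fit_mmrm(
    visits: pd.DataFrame,
    baseline: pd.DataFrame,
    spec: MmrmSpec,
    maxiter: int = 500,
) -> MmrmFit:
    """Maximum-likelihood MMRM fit.

    Returns fixed-effect estimates with their GLS covariance, per-visit
    SDs, Toeplitz lag correlations, and the maximized log-likelihood.
    """
    X, y, pidx, vidx, names, meta = build_design(visits, baseline, spec)
    T = meta["weeks"].size
    data = _PatternData(X, y, pidx, vidx, T)

    # start values: OLS residual SD per visit, zero correlations
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sig0 = np.array(
        [max(resid[vidx == t].std(), 1e-3) if (vidx == t).any() else resid.std() for t in range(T)]
    )
    n_phi = T - 1 if spec.covariance == "toeplitz_h" else 0
    theta0 = np.concatenate((np.log(sig0), np.zeros(n_phi)))

    def objective(theta):
        Sigma, *_ = _theta_to_sigma_matrix(theta, T, spec.covariance)
        try:
            return data.profile_nll(Sigma, reml=spec.reml)
        except np.linalg.LinAlgError:
            return 1e10

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # numerical guards: per-visit SDs bounded relative to the response
        # scale (ML can otherwise spike a sparsely observed visit's SD to
        # zero), and |atanh(pacf)| <= 4 caps each lag correlation at
        # ~0.99933, beyond which the Toeplitz matrix is numerically
        # singular and fits are indistinguishable
        log_sd_y = float(np.log(max(y.std(), 1e-12)))
        bounds = [(log_sd_y - 9.0, log_sd_y + 4.0)] * T + [(-4.0, 4.0)] * n_phi
        theta0[:T] = np.clip(theta0[:T], log_sd_y - 9.0, log_sd_y + 4.0)
        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
    if not np.isfinite(res.fun):
        raise ConvergenceError("MMRM optimization diverged", trace=res)
    Sigma, sig, rho = _theta_to_sigma_matrix(res.x, T, spec.covariance)
    # beta and its covariance are the GLS quantities either way; the
    # reported log-likelihood is the ML one at the optimum
    nll, beta, vcov = data.profile_nll(Sigma, reml=False, want_beta=True)
    loglik = -nll
    phi = np.tanh(res.x[T:]) if spec.covariance == "toeplitz_h" else np.zeros(0)
    spline = meta["spline"]
    fit = MmrmFit(
        spec=MmrmSpec(
            outcome=spec.outcome,
            grouping=spec.grouping,
            covariates=spec.covariates,
            spline=spline,
            covariance=spec.covariance,
            reml=spec.reml,
        ),
        beta=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        sigma=sig,
        rho=rho,
        pacf=phi,
        loglik=float(loglik),
        visit_weeks=meta["weeks"],
        group_levels=meta["levels"],
        covariate_profile=meta["profile"],
        n_obs=data.n_obs,
        n_participants=data.n_participants,
        converged=bool(res.success or np.linalg.norm(res.jac, np.inf) < 1e-2),
        n_iter=int(res.nit),
        message=str(res.message),
    )
    if not fit.converged:
        logger.warning("MMRM optimizer did not report convergence: %s", fit.message)
    return fit


# ---------------------------------------------------------------------------
# Predicted trajectories
# ---------------------------------------------------------------------------


def predict_trajectory(
    fit: MmrmFit, weeks=None, covariate_profile: dict | None = None, z: float = 1.96
) -> pd.DataFrame:
    """Model-implied mean trajectory per group with pointwise 95% CI.

    Covariates are held at the analysis-sample means unless a profile is
    given.  Weeks beyond the boundary knots extrapolate linearly (natural
    constraint) with a warning.
    """
    spec = fit.spec
    weeks = np.asarray(weeks if weeks is not None else fit.visit_weeks, dtype=float)
    spline = spec.spline
    lo, hi = spline.boundary_knots
    if (weeks < lo).any() or (weeks > hi).any():
        warnings.warn("weeks outside boundary knots: linear extrapolation", stacklevel=2)
    basis = natural_spline_basis(weeks, spline)
    profile = dict(fit.covariate_profile)
    if covariate_profile:
        profile.update(covariate_profile)
    rows = []
    names = list(fit.beta.index)
    V = fit.vcov.to_numpy()
    for lev in fit.group_levels:
        for w, brow in zip(weeks, basis):
            x = np.zeros(len(names))
            x[names.index(f"{spec.grouping}[{lev}]")] = 1.0
            for j in range(basis.shape[1]):
                x[names.index(f"{spec.grouping}[{lev}]:ns{j + 1}")] = brow[j]
            for c in spec.covariates:
                # design columns were centered at the sample mean
                x[names.index(c)] = profile[c] - fit.covariate_profile[c]
            mean = float(x @ fit.beta.to_numpy())
            se = float(np.sqrt(x @ V @ x))
            rows.append(
                {
                    "group": lev,
                    "week": w,
                    "mean": mean,
                    "se": se,
                    "lo": mean - z * se,
                    "hi": mean + z * se,
                }
            )
    return pd.DataFrame(rows)
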