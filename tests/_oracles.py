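"""Independent reference implementations used as oracles.

Each function here deliberately avoids the code path it checks: the
commonality oracle solves a linear system instead of inclusion-exclusion,
the likelihood oracle assembles the dense joint covariance, the AUC oracle
enumerates pairs, the progression oracle is a literal transcription of the
endpoint rule, and the KM oracle is the hand product-limit recursion.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import multivariate_normal


# ---------------------------------------------------------------------------
# Commonality: solve R²(S) = sum_{A : A ∩ S != 0} C(A) for all non-empty S
# ---------------------------------------------------------------------------


def commonality_by_linear_system(r2_by_mask: dict[int, float], p: int) -> dict[int, float]:
    masks = list(range(1, 1 << p))
    M = np.zeros((len(masks), len(masks)))
    rhs = np.array([r2_by_mask[S] for S in masks])
    for i, S in enumerate(masks):
        for j, A in enumerate(masks):
            if A & S:
                M[i, j] = 1.0
    C = np.linalg.solve(M, rhs)
    return {A: C[j] for j, A in enumerate(masks)}


def r2_by_qr(y: np.ndarray, X: np.ndarray) -> float:
    """R² of OLS with intercept via explicit QR."""
    n = len(y)
    Z = np.column_stack([np.ones(n), X])
    Q, _ = np.linalg.qr(Z)
    fitted = Q @ (Q.T @ y)
    yc = y - y.mean()
    return 1.0 - float(((y - fitted) ** 2).sum()) / float((yc**2).sum())


def all_subsets_r2_brute(y: np.ndarray, X: np.ndarray) -> dict[int, float]:
    p = X.shape[1]
    out = {}
    for mask in range(1, 1 << p):
        cols = [i for i in range(p) if mask >> i & 1]
        out[mask] = r2_by_qr(y, X[:, cols])
    return out


# ---------------------------------------------------------------------------
# Dense Gaussian likelihood for the MMRM
# ---------------------------------------------------------------------------


def dense_mmrm_loglik(y, X, beta, pidx, vidx, Sigma) -> float:
    """Joint log density of all participants, each via scipy's dense MVN."""
    total = 0.0
    resid = y - X @ beta
    for pid in np.unique(pidx):
        m = pidx == pid
        idx = vidx[m]
        order = np.argsort(idx)
        sub = Sigma[np.ix_(idx[order], idx[order])]
        total += multivariate_normal.logpdf(resid[m][order], mean=np.zeros(m.sum()), cov=sub)
    return float(total)


# ---------------------------------------------------------------------------
# Pairwise AUC
# ---------------------------------------------------------------------------


def auc_by_pairs(scores, labels) -> float:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Progression rule, literal transcription
# ---------------------------------------------------------------------------


def progression_brute(weeks, ratings, final_week):
    """Event if two consecutive attended ratings > 0 (dated at the second),
    else if the last rating > 0 and it falls at the scheduled final week;
    otherwise censored at the last attended week."""
    for i in range(len(ratings) - 1):
        if ratings[i] > 0 and ratings[i + 1] > 0:
            return True, weeks[i + 1]
    if ratings[-1] > 0 and weeks[-1] >= final_week:
        return True, weeks[-1]
    return False, weeks[-1]


def enumerate_cdr_series(max_len=5, final_week=192, gap=48):
    """All CDR series of length 2..max_len starting (0, rating 0), ratings
    in {0, 0.5}, on the annual grid."""
    for L in range(2, max_len + 1):
        weeks = [gap * i for i in range(L)]
        for tail in itertools.product([0.0, 0.5], repeat=L - 1):
            yield weeks, [0.0, *tail]


# ---------------------------------------------------------------------------
# Product-limit by hand
# ---------------------------------------------------------------------------


def km_by_hand(times, events):
    """Survival at each distinct event time: S *= (1 - d/n)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = {}
    s = 1.0
    for t in np.unique(times[events]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_at_risk
        out[float(t)] = s
    return out


# ---------------------------------------------------------------------------
# Natural-spline space via natural interpolating splines
# ---------------------------------------------------------------------------


def natural_spline_span(knots, grid):
    """Columns spanning the natural cubic spline space with the given
    knots, built from natural interpolating splines of the unit vectors at
    the knots (valid inside the boundary knots)."""
    from scipy.interpolate import CubicSpline

    knots = np.asarray(knots, dtype=float)
    cols = []
    for j in range(knots.size):
        e = np.zeros(knots.size)
        e[j] = 1.0
        cs = CubicSpline(knots, e, bc_type="natural")
        cols.append(cs(grid))
    return np.column_stack(cols)
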