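"""Natural cubic spline time bases for longitudinal trajectory models.

A natural cubic spline is a piecewise cubic polynomial, twice continuously
differentiable, constrained to be *linear* beyond its boundary knots.  With
boundary knots at the first and last scheduled visit and ``df - 1`` interior
knots, the basis (excluding the intercept) has exactly ``df`` columns; the
trajectory models here use ``df = 2`` (one interior knot), i.e. "two spline
basis expansion terms for time".

The construction is the classical truncated-power one (as in R's ``ns``):
with knots :math:`k_1 < \\dots < k_K` (boundary knots included), define

.. math::

    d_j(x) = \\frac{(x - k_j)_+^3 - (x - k_K)_+^3}{k_K - k_j},

and take basis columns :math:`x` and :math:`d_j(x) - d_{K-1}(x)` for
:math:`j = 1, \\dots, K-2`.  Each column has zero second derivative outside
the boundary knots, which gives linear extrapolation for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SplineSpecError(ValueError):
    """Inconsistent degrees of freedom / knot configuration."""


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for a natural cubic spline time basis.

    Parameters
    ----------
    df : int
        Number of basis columns (intercept excluded).  Must equal
        ``len(interior_knots) + 1``.
    interior_knots : tuple of float
        Knot positions strictly inside the boundary knots, in weeks.
    boundary_knots : tuple of float
        ``(low, high)`` — the spline is linear beyond these.
    """

    df: int = 2
    interior_knots: tuple[float, ...] = (120.0,)
    boundary_knots: tuple[float, float] = (0.0, 240.0)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise SplineSpecError(f"boundary knots must be increasing, got {self.boundary_knots}")
        interior = tuple(sorted(self.interior_knots))
        if any(not (lo < k < hi) for k in interior):
            raise SplineSpecError(
                f"interior knots {interior} must lie strictly inside boundaries {self.boundary_knots}"
            )
        if len(set(interior)) != len(interior):
            raise SplineSpecError("interior knots must be distinct")
        if self.df != len(interior) + 1:
            raise SplineSpecError(
                f"df={self.df} inconsistent with {len(interior)} interior knot(s); "
                "a natural cubic spline basis (no intercept) has df = n_interior + 1"
            )
        object.__setattr__(self, "interior_knots", interior)

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray((self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]))

    @classmethod
    def from_weeks(cls, weeks, df: int = 2) -> "SplineSpec":
        """Default knot layout for a visit schedule: boundary knots at the
        min/max scheduled week, interior knots at quantiles of the schedule
        (the median for ``df=2``)."""
        w = np.unique(np.asarray(weeks, dtype=float))
        if w.size < 3:
            raise SplineSpecError("need at least 3 distinct weeks to place knots")
        probs = np.arange(1, df) / df
        interior = np.quantile(w, probs)
        # nudge interior knots off the boundaries if the schedule is tiny
        lo, hi = w[0], w[-1]
        interior = np.clip(interior, lo + 1e-8 * (hi - lo), hi - 1e-8 * (hi - lo))
        return cls(df=df, interior_knots=tuple(interior), boundary_knots=(lo, hi))


def natural_spline_basis(weeks, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``weeks``.

    Returns an ``(len(weeks), spec.df)`` matrix whose columns span the
    natural-spline space (intercept excluded).  Weeks outside the boundary
    knots are evaluated by the spline's own linear extrapolation.
    """
    x = np.asarray(weeks, dtype=float).ravel()
    knots = spec.all_knots
    K = knots.size
    kK, kK1 = knots[-1], knots[-2]

    def d(j: int) -> np.ndarray:
        return (np.maximum(x - knots[j], 0.0) ** 3 - np.maximum(x - kK, 0.0) ** 3) / (kK - knots[j])

    cols = [x]
    dlast = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dlast)
    basis = np.column_stack(cols)
    # rescale to keep columns O(1): weeks are O(100), cubics O(1e4)
    scale = np.maximum(np.abs(knots).max(), 1.0)
    basis[:, 0] /= scale
    basis[:, 1:] /= scale**2 if K > 2 else 1.0
    return basis
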