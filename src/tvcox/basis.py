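"""B-spline basis spanning the time-varying coefficient functions.

Each covariate's log hazard ratio is modelled as beta_j(t) = sum_k theta_jk
B_k(t) on the span of the observed distinct event times. The basis is a
clamped B-spline family (scipy.interpolate.BSpline underneath): K functions
of a given degree, interior knots placed by default at quantiles of the
distinct event times, boundary knots at the smallest and largest distinct
event time with multiplicity degree+1. The functions are non-negative and
form a partition of unity on the boundary interval.

Evaluation outside the interval clamps to the boundary by default (constant
extrapolation of the coefficient functions) — needed when predicting at
censoring times beyond the last event. Pass ``clamp=False`` to make
out-of-range times an error instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "make_basis"]


@dataclass
class SplineBasis:
    """K B-spline basis functions on [t_min, t_max].

    Attributes
    ----------
    degree
        Polynomial degree (3 = cubic, the default family).
    interior_knots
        Ascending interior knots (may be empty).
    boundary
        ``(t_min, t_max)`` covering all distinct event times.
    knot_rule
        ``"quantile"`` or ``"uniform"`` — how the interior knots were placed.
    """

    degree: int
    interior_knots: np.ndarray
    boundary: tuple[float, float]
    knot_rule: str = "quantile"
    knots: np.ndarray = field(init=False)  # full clamped knot vector

    def __post_init__(self) -> None:
        t_min, t_max = map(float, self.boundary)
        if not t_max > t_min:
            raise ValueError(f"degenerate basis interval [{t_min}, {t_max}]")
        self.interior_knots = np.asarray(self.interior_knots, dtype=float)
        if np.any(self.interior_knots <= t_min) or np.any(self.interior_knots >= t_max):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if np.any(np.diff(self.interior_knots) < 0):
            raise ValueError("interior knots must be ascending")
        self.boundary = (t_min, t_max)
        self.knots = np.concatenate(
            [
                np.repeat(t_min, self.degree + 1),
                self.interior_knots,
                np.repeat(t_max, self.degree + 1),
            ]
        )

    @property
    def K(self) -> int:
        """Number of basis functions: interior knots + degree + 1."""
        return self.interior_knots.shape[0] + self.degree + 1

    def _clamp(self, times, clamp: bool) -> np.ndarray:
        t = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.boundary
        if clamp:
            return np.clip(t, lo, hi)
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(
                f"time outside basis range [{lo}, {hi}] with clamping disabled"
            )
        return t

    def evaluate(self, times, clamp: bool = True) -> np.ndarray:
        """Design matrix of shape (len(times), K); rows sum to 1."""
        t = self._clamp(times, clamp)
        spl = BSpline(self.knots, np.eye(self.K), self.degree, extrapolate=True)
        return spl(t)

    def derivative(self, times, order: int = 1, clamp: bool = True) -> np.ndarray:
        """Matrix of order-th derivatives, shape (len(times), K)."""
        if order < 0:
            raise ValueError("derivative order must be >= 0")
        if order == 0:
            return self.evaluate(times, clamp=clamp)
        if order > self.degree:
            raise ValueError(
                f"derivative order {order} exceeds basis degree {self.degree}"
            )
        t = self._clamp(times, clamp)
        spl = BSpline(self.knots, np.eye(self.K), self.degree, extrapolate=True)
        return spl.derivative(order)(t)

    def greville(self) -> np.ndarray:
        """Greville abscissae (knot averages); reproduce t for degree >= 1."""
        if self.degree == 0:
            return 0.5 * (self.knots[:-1] + self.knots[1:])
        k = self.degree
        return np.array(
            [self.knots[i + 1 : i + k + 1].mean() for i in range(self.K)]
        )


def make_basis(
    event_times,
    K: int = 8,
    degree: int = 3,
    knot_rule: str = "quantile",
) -> SplineBasis:
    """Construct the basis from the observed distinct event times.

    Interior knots sit at equally spaced quantiles (default) or equally
    spaced points of the distinct event times' range; boundary knots at the
    smallest and largest distinct event time. ``K`` between 5 and 10 is the
    usual working range for time-varying effects; larger K gives more
    flexibility and relies on the penalty for stability.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if K < degree + 1:
        raise ValueError(f"K={K} too small for degree {degree}: need K >= degree+1")
    if knot_rule not in ("quantile", "uniform"):
        raise ValueError(f"unknown knot rule {knot_rule!r}")
    distinct = np.unique(np.asarray(event_times, dtype=float))
    if distinct.shape[0] < 2:
        raise ValueError("need at least 2 distinct event times to span a basis")
    n_interior = K - degree - 1
    if knot_rule == "quantile" and distinct.shape[0] - 2 < n_interior:
        raise ValueError(
            f"{distinct.shape[0]} distinct event times cannot support "
            f"{n_interior} interior quantile knots; reduce K"
        )
    t_min, t_max = float(distinct[0]), float(distinct[-1])
    if n_interior == 0:
        interior = np.empty(0)
    elif knot_rule == "quantile":
        q = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(distinct, q)
    else:
        interior = t_min + (t_max - t_min) * np.arange(1, n_interior + 1) / (
            n_interior + 1
        )
    # quantile knots can collide on heavily tied grids; nudge into strict interior
    interior = np.clip(
        interior, np.nextafter(t_min, t_max), np.nextafter(t_max, t_min)
    )
    return SplineBasis(
        degree=degree,
        interior_knots=interior,
        boundary=(t_min, t_max),
        knot_rule=knot_rule,
    )
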