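"""Growth-rate estimation, relative fitness, generations, and monotone
fitness trajectories for serially transferred bacterial populations.

Fitness here is the exponential-phase growth rate; relative fitness divides
a population's rate by the wild-type ancestor's rate measured under the
same conditions, and generations per culture cycle are counted as
``log2(final density / initial density)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import linregress
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "GrowthCurve",
    "FitnessPoint",
    "GrowthRateEstimator",
    "growth_rate",
    "relative_fitness",
    "generations",
    "cumulative_generations",
    "MonotoneTrajectory",
    "monotone_fitness_trajectory",
]


@dataclass
class GrowthCurve:
    """An OD600 time series: times in minutes (strictly increasing), OD >= 0."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-D of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0) or not np.all(np.isfinite(self.od)):
            raise ValueError("od must be finite and non-negative")


@dataclass
class FitnessPoint:
    """Fitness of one population at one time point of the evolution."""

    day: float
    growth_rate: float
    relative_fitness: float
    n_replicates: int = 1


class GrowthRateEstimator(BaseEstimator):
    """Maximum specific growth rate from a sliding log-linear fit.

    Over every run of ``window_points`` consecutive measurements with
    OD above ``od_floor``, ordinary least squares of ln(OD) on time is
    fitted; the estimate is the largest slope among windows whose R^2
    reaches ``r2_min``.  If no window passes, the best-R^2 window's slope
    is returned and ``low_quality_`` is set (with a warning).

    Attributes
    ----------
    rate_ : float
        Growth rate in h^-1.
    r_squared_ : float
        R^2 of the selected window.
    window_ : (int, int)
        Index range (half-open) of the selected window in the input curve.
    low_quality_ : bool
        True when no window met ``r2_min``.
    """

    def __init__(self, window_points: int = 5, r2_min: float = 0.99,
                 od_floor: float = 0.01):
        self.window_points = window_points
        self.r2_min = r2_min
        self.od_floor = od_floor

    def fit(self, curve: GrowthCurve, y=None) -> "GrowthRateEstimator":
        w = self.window_points
        usable = curve.od > self.od_floor
        candidates: list[tuple[float, float, int]] = []  # (slope/min, r2, start)
        for start in range(len(curve.od) - w + 1):
            if not usable[start:start + w].all():
                continue
            t = curve.times[start:start + w]
            ln_od = np.log(curve.od[start:start + w])
            res = linregress(t, ln_od)
            sst = float(np.sum((ln_od - ln_od.mean()) ** 2))
            if sst == 0:
                r2 = 1.0  # perfectly flat window: zero residual by definition
            else:
                r2 = float(res.rvalue ** 2)
            candidates.append((float(res.slope), r2, start))
        if not candidates:
            raise ValueError(
                f"no run of {w} consecutive points with OD > {self.od_floor}"
            )
        passing = [c for c in candidates if c[1] >= self.r2_min]
        if passing:
            slope, r2, start = max(passing, key=lambda c: c[0])
            self.low_quality_ = False
        else:
            slope, r2, start = max(candidates, key=lambda c: c[1])
            self.low_quality_ = True
            warnings.warn(
                f"no {w}-point window reached R^2 >= {self.r2_min}; "
                "returning the best-R^2 window's slope", stacklevel=2,
            )
        self.rate_ = slope * 60.0  # per-minute slope -> h^-1
        self.r_squared_ = r2
        self.window_ = (start, start + w)
        return self


def growth_rate(curve: GrowthCurve, window_points: int = 5, r2_min: float = 0.99,
                od_floor: float = 0.01) -> float:
    """Maximum specific growth rate (h^-1); see :class:`GrowthRateEstimator`."""
    est = GrowthRateEstimator(window_points, r2_min, od_floor).fit(curve)
    return est.rate_


def relative_fitness(mu: float, mu_ref: float) -> float:
    """Growth rate divided by the reference (ancestor) growth rate."""
    if mu_ref <= 0:
        raise ValueError("reference growth rate must be positive")
    return mu / mu_ref


def generations(od_initial: float, od_final: float) -> float:
    """Doublings in one culture cycle: log2(final density / initial density)."""
    if od_initial <= 0 or od_final <= 0:
        raise ValueError("cell densities must be positive")
    return math.log2(od_final / od_initial)


def cumulative_generations(cycles: Iterable[Tuple[float, float]]) -> float:
    """Total generations over serial transfers: sum of per-cycle doublings."""
    return sum(generations(a, b) for a, b in cycles)


class MonotoneTrajectory(BaseEstimator, RegressorMixin):
    """Monotone non-decreasing fitness trajectory through noisy time points.

    Fitness values are first projected onto the nearest non-decreasing
    sequence (isotonic regression, pool-adjacent-violators), then a
    shape-preserving monotone interpolant (piecewise-cubic Hermite) is
    passed exactly through the projected knots.  The fitted curve is
    non-decreasing everywhere and reproduces the projected knot values on
    the knot days.

    Attributes
    ----------
    knots_x_ : ndarray   -- knot days
    knots_y_ : ndarray   -- isotonic-projected fitness at the knots
    """

    def __init__(self):
        pass

    def fit(self, days: Sequence[float], fitness: Sequence[float]) -> "MonotoneTrajectory":
        x = np.asarray(days, dtype=float)
        y = np.asarray(fitness, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("days and fitness must be 1-D of equal length")
        if len(x) < 3:
            raise ValueError("need at least 3 points")
        if np.any(np.diff(x) == 0):
            raise ValueError("duplicate days")
        if np.any(np.diff(x) < 0):
            raise ValueError("days must be strictly increasing")
        proj = IsotonicRegression(increasing=True).fit_transform(x, y)
        self.knots_x_ = x
        self.knots_y_ = np.asarray(proj, dtype=float)
        self._interp = PchipInterpolator(x, self.knots_y_, extrapolate=True)
        return self

    def predict(self, grid: Sequence[float]) -> np.ndarray:
        g = np.asarray(grid, dtype=float)
        out = self._interp(g)
        # PCHIP on monotone knots is monotone; clip extrapolation flat.
        lo, hi = self.knots_x_[0], self.knots_x_[-1]
        out = np.where(g < lo, self.knots_y_[0], out)
        out = np.where(g > hi, self.knots_y_[-1], out)
        return out


def monotone_fitness_trajectory(
    points: Sequence[Tuple[float, float]], grid: Sequence[float]
) -> np.ndarray:
    """Fit a monotone trajectory through (day, relative fitness) points and
    evaluate it on ``grid``; see :class:`MonotoneTrajectory`."""
    days = [p[0] for p in points]
    fitness = [p[1] for p in points]
    return MonotoneTrajectory().fit(days, fitness).predict(grid)
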