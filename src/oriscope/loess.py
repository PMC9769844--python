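"""Locally estimated scatterplot smoothing (LOESS) for coverage profiles.

Local weighted polynomial regression with tricube weights over the
``ceil(span * n)`` nearest points, evaluated at each target point.  This is
the smoother applied to normalized copy-number landscapes before peak and
trough calling; defaults (span 0.3, local quadratic, gaussian fitting, no
robustness iterations) mirror the conventional statistical-environment
defaults for this analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["LoessSmoother", "loess_fit", "LoessFit", "loess_smooth"]


def _nearest_block(x: np.ndarray, x0: float, k: int) -> tuple[int, int]:
    """Half-open index range of the k nearest points to x0 (x sorted)."""
    i = int(np.searchsorted(x, x0))
    lo = hi = min(i, len(x) - 1)
    hi = lo  # expand [lo, hi) greedily toward the nearer neighbour
    while hi - lo < k:
        if lo == 0:
            hi += 1
        elif hi == len(x):
            lo -= 1
        elif x0 - x[lo - 1] <= x[hi] - x0:
            lo -= 1
        else:
            hi += 1
    return lo, hi


def _tricube(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    w = (1.0 - (d / dmax) ** 3) ** 3
    return np.clip(w, 0.0, None)


def _wls_at_zero(u: np.ndarray, y: np.ndarray, w: np.ndarray, degree: int) -> float:
    """Weighted polynomial fit on centered abscissa u; value at u = 0."""
    sw = np.sqrt(w)
    A = np.vander(u, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    return float(beta[0])


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    x_eval: Sequence[float] | None = None,
    span: float = 0.3,
    degree: int = 2,
    k: int | None = None,
) -> np.ndarray:
    """LOESS fit of ``y`` on sorted abscissa ``x``, evaluated at ``x_eval``.

    The neighbourhood of each evaluation point is its ``ceil(span * n)``
    nearest training points (never fewer than ``degree + 2``); weights are
    tricube in distance scaled by the farthest neighbour.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D of equal length")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = len(x)
    if k is None:
        k = int(np.ceil(span * n))
    k = min(n, max(k, degree + 2))
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points")
    xe = x if x_eval is None else np.asarray(x_eval, dtype=float)

    # Uniform-grid fast path: interior points share one equivalent kernel.
    if x_eval is None and n > 2 * k and _is_uniform(x):
        return _loess_uniform(x, y, k, degree)

    out = np.empty(len(xe))
    for j, x0 in enumerate(xe):
        lo, hi = _nearest_block(x, x0, k)
        u = x[lo:hi] - x0
        w = _tricube(np.abs(u))
        out[j] = _wls_at_zero(u, y[lo:hi], w, degree)
    return out


def _is_uniform(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.allclose(d, d[0], rtol=0, atol=1e-9 * max(abs(d[0]), 1.0)))


def _loess_uniform(x: np.ndarray, y: np.ndarray, k: int, degree: int) -> np.ndarray:
    """Equivalent-kernel convolution for evenly spaced x evaluated at x.

    For interior points the k-nearest block is always the same centered
    index pattern, so the fitted value is a fixed linear combination of the
    block's y values; boundary points fall back to individual fits.
    Numerically identical to the generic path.
    """
    n = len(x)
    step = x[1] - x[0]
    half = (k - 1) // 2  # two-pointer expansion prefers the left on ties
    left = k - 1 - half
    out = np.empty(n)
    # interior kernel: offsets -left .. +half around the eval point
    u = np.arange(-left, half + 1, dtype=float) * step
    w = _tricube(np.abs(u))
    A = np.vander(u, degree + 1, increasing=True)
    Aw = A * w[:, None]
    beta_map = np.linalg.solve(A.T @ Aw, Aw.T)  # rows: coefficients -> y
    kernel = beta_map[0]  # equivalent kernel for the value at u = 0
    interior = np.arange(left, n - half)
    out[interior] = np.convolve(y, kernel[::-1], mode="valid")
    for j in list(range(left)) + list(range(n - half, n)):
        lo, hi = _nearest_block(x, x[j], k)
        uu = x[lo:hi] - x[j]
        out[j] = _wls_at_zero(uu, y[lo:hi], _tricube(np.abs(uu)), degree)
    return out


@dataclass
class LoessFit:
    """Smoothed profile values at window midpoints."""

    fitted: np.ndarray
    span: float
    degree: int
    circular: bool
    window: int
    genome_length: int

    @property
    def midpoints(self) -> np.ndarray:
        starts = np.arange(len(self.fitted), dtype=np.int64) * self.window
        ends = np.minimum(starts + self.window, self.genome_length)
        return (starts + ends) / 2.0

    def value_at(self, position: float) -> float:
        """Fitted value of the window containing a genomic position."""
        if not (0 <= position < self.genome_length):
            raise ValueError("position outside genome")
        return float(self.fitted[int(position // self.window)])


class LoessSmoother(BaseEstimator):
    """LOESS smoother for windowed copy-number profiles.

    Parameters
    ----------
    span : float
        Fraction of windows in each local neighbourhood, in (0, 1].
    degree : int
        Local polynomial degree (1 or 2).
    circular : bool
        If True, wrap ``ceil(span*n)/2`` windows from each end before
        fitting so neighbourhoods cross the coordinate origin — appropriate
        for circular chromosomes with a feature near position 0.

    Attributes
    ----------
    fitted_ : ndarray
        Smoothed values at window midpoints after :meth:`fit`.
    """

    def __init__(self, span: float = 0.3, degree: int = 2, circular: bool = False):
        self.span = span
        self.degree = degree
        self.circular = circular

    def fit(self, profile, y=None) -> "LoessSmoother":
        """Smooth a :class:`~oriscope.coverage.NormalizedProfile` (or raw track)."""
        values = np.asarray(profile.values, dtype=float)
        n = len(values)
        mid = profile.midpoints
        if self.circular:
            k = max(int(np.ceil(self.span * n)), self.degree + 2)
            pad = min(n, (k + 1) // 2 + 1)
            x = np.concatenate(
                [mid[-pad:] - profile.genome_length, mid, mid[:pad] + profile.genome_length]
            )
            yv = np.concatenate([values[-pad:], values, values[:pad]])
            fitted = loess_fit(x, yv, x_eval=mid, degree=self.degree, k=k)
        else:
            fitted = loess_fit(mid, values, span=self.span, degree=self.degree)
        self.fitted_ = fitted
        self.result_ = LoessFit(
            fitted=fitted,
            span=self.span,
            degree=self.degree,
            circular=self.circular,
            window=profile.window,
            genome_length=profile.genome_length,
        )
        return self

    def fit_result(self, profile) -> LoessFit:
        return self.fit(profile).result_


def loess_smooth(
    profile, span: float = 0.3, degree: int = 2, circular: bool = False
) -> LoessFit:
    """Functional wrapper over :class:`LoessSmoother`."""
    return LoessSmoother(span=span, degree=degree, circular=circular).fit_result(profile)
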