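"""Steady-state replication model for circular bacterial chromosomes.

A chromosome with one or more synchronously firing origins is replicated by
forks that proceed bidirectionally at constant speed and annihilate where
they meet.  In a steady-state exponential culture the relative copy number
of a locus replicated ``t`` minutes after initiation is ``2**((C - t)/tau)``
where ``C`` is the replication time of the last-replicated locus and ``tau``
the population doubling time — the classical Cooper–Helmstetter relation.
These closed forms are the ground truth behind every simulated coverage
track in :mod:`oriscope.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["ChromosomeSpec", "replication_time", "expected_copy_number"]

#: E. coli K-12 MG1655 chromosome length (bp) and oriC midpoint, used by the
#: convenience constructors.  Fork speed ~58 kb/min corresponds to the
#: commonly cited ~1 kb/s replisome speed.
MG1655_LENGTH = 4_641_652
MG1655_ORIC = 3_925_744
MG1655_FORK_SPEED = 58_000.0

# Insertion loci of the two extra oriC-mioC copies in the triple-origin
# derivative: the lacZ locus and the dadX/cvrA intergenic region.
EXTRA_ORIGIN_LACZ = 365_000
EXTRA_ORIGIN_DADX = 1_240_000


@dataclass(frozen=True)
class ChromosomeSpec:
    """Circular chromosome with synchronously firing replication origins.

    Parameters
    ----------
    length : int
        Chromosome length in bp.
    origins : tuple of int
        Origin positions, 0-based on ``[0, length)``; must be distinct.
    fork_speed : float
        Replication fork speed in bp/min (> 0).
    doubling_time : float
        Population doubling time ``tau`` in min (> 0).
    duplication : (start, end, multiplier), optional
        Half-open segmental duplication; ``start > end`` wraps through the
        origin of coordinates.  Applied as a copy-number multiplier on top
        of the replication landscape.
    """

    length: int
    origins: Tuple[int, ...]
    fork_speed: float
    doubling_time: float
    duplication: Optional[Tuple[int, int, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "origins", tuple(int(o) for o in self.origins))
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not self.origins:
            raise ValueError("at least one origin is required")
        if len(set(self.origins)) != len(self.origins):
            raise ValueError("origins must be distinct")
        for o in self.origins:
            if not (0 <= o < self.length):
                raise ValueError(f"origin {o} outside [0, {self.length})")
        if not (np.isfinite(self.fork_speed) and self.fork_speed > 0):
            raise ValueError("fork_speed must be finite and positive")
        if not (np.isfinite(self.doubling_time) and self.doubling_time > 0):
            raise ValueError("doubling_time must be finite and positive")
        if self.duplication is not None:
            start, end, mult = self.duplication
            if not (0 <= start < self.length and 0 <= end <= self.length):
                raise ValueError("duplication interval outside chromosome")
            if mult < 1:
                raise ValueError("duplication multiplier must be >= 1")

    # ------------------------------------------------------------------
    @property
    def max_replication_time(self) -> float:
        """Replication time ``C`` (min) of the last-replicated locus.

        Forks from adjacent origins meet midway (in time) through the gap
        between them, so the maximum is attained at the midpoint of the
        largest inter-origin arc.
        """
        ori = np.sort(np.asarray(self.origins))
        gaps = np.diff(np.concatenate([ori, [ori[0] + self.length]]))
        return float(gaps.max() / 2.0 / self.fork_speed)

    def duplication_multiplier(self, x: np.ndarray) -> np.ndarray:
        """Copy-number multiplier at positions ``x`` (1 outside the segment)."""
        x = np.asarray(x)
        m = np.ones(x.shape, dtype=float)
        if self.duplication is None:
            return m
        start, end, mult = self.duplication
        if start <= end:
            inside = (x >= start) & (x < end)
        else:  # wraps through coordinate origin
            inside = (x >= start) | (x < end)
        m[inside] = mult
        return m

    # -- convenience constructors --------------------------------------
    @classmethod
    def single_origin(
        cls,
        length: int = MG1655_LENGTH,
        origin: int = MG1655_ORIC,
        fork_speed: float = MG1655_FORK_SPEED,
        doubling_time: float = 40.0,
        duplication: Optional[Tuple[int, int, float]] = None,
    ) -> "ChromosomeSpec":
        """Wild-type-like chromosome with a single oriC."""
        return cls(length, (origin,), fork_speed, doubling_time, duplication)

    @classmethod
    def triple_origin(
        cls,
        length: int = MG1655_LENGTH,
        origins: Sequence[int] = (EXTRA_ORIGIN_LACZ, EXTRA_ORIGIN_DADX, MG1655_ORIC),
        fork_speed: float = MG1655_FORK_SPEED,
        doubling_time: float = 40.0,
        duplication: Optional[Tuple[int, int, float]] = None,
    ) -> "ChromosomeSpec":
        """Derivative carrying two extra oriC-mioC insertions (lacZ, dadX/cvrA)."""
        return cls(length, tuple(origins), fork_speed, doubling_time, duplication)


def _circular_distance(length: int, a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(a - b) % length
    return np.minimum(d, length - d)


def replication_time(spec: ChromosomeSpec, x) -> np.ndarray | float:
    """Minutes after synchronous initiation at which locus ``x`` is replicated.

    The arrival time is the minimum over origins of the shorter circular
    arc distance divided by the fork speed; it is zero at every origin,
    continuous, and piecewise linear in ``x``.

    Parameters
    ----------
    spec : ChromosomeSpec
    x : scalar or array of positions in bp, each in ``[0, length)``.
    """
    scalar = np.isscalar(x)
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any((xa < 0) | (xa >= spec.length)):
        raise ValueError("position outside [0, length)")
    d = np.min(
        [_circular_distance(spec.length, xa, o) for o in spec.origins], axis=0
    )
    t = d / spec.fork_speed
    return float(t[0]) if scalar else t


def expected_copy_number(spec: ChromosomeSpec, x) -> np.ndarray | float:
    """Steady-state relative copy number of locus ``x``.

    ``c(x) = m(x) * 2**((C - t(x)) / tau)`` with ``C`` the maximum
    replication time, ``tau`` the doubling time, and ``m`` the duplication
    multiplier.  Only ratios of ``c`` are meaningful; the last-replicated
    locus has ``c = 1`` (absent duplication) and the origin
    ``c = 2**(C/tau)``.
    """
    scalar = np.isscalar(x)
    t = np.atleast_1d(replication_time(spec, x))
    c = 2.0 ** ((spec.max_replication_time - t) / spec.doubling_time)
    c = c * spec.duplication_multiplier(np.atleast_1d(np.asarray(x, dtype=float)))
    return float(c[0]) if scalar else c
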