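"""Windowed genome-coverage containers and plain-text readers/writers."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "WindowedCoverage",
    "NormalizedProfile",
    "normalize_coverage",
    "read_bedgraph",
    "write_bedgraph",
    "read_window_tsv",
    "write_window_tsv",
]


@dataclass
class WindowedCoverage:
    """Mean per-base coverage in consecutive fixed-width genome windows.

    ``values[i]`` is the mean coverage of the half-open window
    ``[i*window, min((i+1)*window, genome_length))``; the final window may
    be short.
    """

    genome_length: int
    window: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_expected = math.ceil(self.genome_length / self.window)
        if len(self.values) != n_expected:
            raise ValueError(
                f"expected {n_expected} windows for length {self.genome_length}"
                f" at window {self.window}, got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("coverage values must be finite and non-negative")

    @property
    def n_windows(self) -> int:
        return len(self.values)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows, dtype=np.int64) * self.window

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.window, self.genome_length)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def window_index(self, position: float) -> int:
        """Index of the window containing a genomic position."""
        if not (0 <= position < self.genome_length):
            raise ValueError("position outside genome")
        return int(position // self.window)


@dataclass
class NormalizedProfile(WindowedCoverage):
    """Normalized copy-number profile: window coverages scaled to sum to 1.

    Dividing each window's mean coverage by the total over all windows
    makes profiles from libraries of different depth directly comparable
    while preserving every between-window ratio.
    """

    @property
    def c(self) -> np.ndarray:
        return self.values


def normalize_coverage(cov: WindowedCoverage) -> NormalizedProfile:
    """Divide each window's mean coverage by the total over windows.

    Raises
    ------
    ValueError
        If the coverage track is all-zero (normalization undefined).
    """
    total = cov.values.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero coverage track")
    return NormalizedProfile(cov.genome_length, cov.window, cov.values / total)


# ---------------------------------------------------------------------------
# plain-text adapters

PathLike = Union[str, Path]


def write_bedgraph(cov: WindowedCoverage, path: PathLike, chrom: str = "chr") -> None:
    df = pd.DataFrame(
        {"chrom": chrom, "start": cov.starts, "end": cov.ends, "value": cov.values}
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: PathLike, window: int | None = None) -> WindowedCoverage:
    """Read a single-chromosome bedGraph of equal-width windows."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    if df["chrom"].nunique() != 1:
        raise ValueError("expected a single-chromosome bedGraph")
    df = df.sort_values("start")
    widths = (df["end"] - df["start"]).to_numpy()
    if window is None:
        window = int(widths[0])
    if not np.all(widths[:-1] == window):
        raise ValueError("bedGraph windows are not equal-width")
    return WindowedCoverage(int(df["end"].iloc[-1]), window, df["value"].to_numpy())


def write_window_tsv(cov: WindowedCoverage, path: PathLike) -> None:
    pd.DataFrame(
        {"window_start": cov.starts, "mean_coverage": cov.values}
    ).to_csv(path, sep="\t", index=False)


def read_window_tsv(path: PathLike, genome_length: int | None = None) -> WindowedCoverage:
    df = pd.read_csv(path, sep="\t")
    for col in ("window_start", "mean_coverage"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    df = df.sort_values("window_start")
    starts = df["window_start"].to_numpy()
    if len(starts) < 2:
        raise ValueError("need at least two windows")
    window = int(starts[1] - starts[0])
    if genome_length is None:
        genome_length = int(starts[-1] + window)
    return WindowedCoverage(genome_length, window, df["mean_coverage"].to_numpy())
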