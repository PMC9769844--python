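"""Synthetic data generators with the statistical structure the analysis
pipeline assumes.

Coverage tracks follow the steady-state exponential-culture copy-number
landscape of :mod:`oriscope.chromosome` with multinomial read sampling;
growth curves are exponential-then-saturating OD600 series on a 30-min
cadence; count matrices are negative-binomial with a planted per-population
expression shift that scales with fitness gain; all draws flow from one
explicit seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
import pandas as pd

from .chromosome import ChromosomeSpec, expected_copy_number
from .coverage import WindowedCoverage
from .growth import GrowthCurve

__all__ = [
    "CoverageSimConfig",
    "GrowthSimConfig",
    "PopulationDesign",
    "ExpressionDesign",
    "simulate_coverage",
    "expected_coverage",
    "simulate_growth_curve",
    "simulate_counts",
    "default_expression_design",
    "write_growth_tsv",
    "write_counts_tsv",
    "write_meta_tsv",
]


# ---------------------------------------------------------------------------
# coverage


@dataclass(frozen=True)
class CoverageSimConfig:
    """Sequencing-coverage simulation settings.

    ``noise="poisson"`` distributes reads multinomially across windows
    (conserving ``n_reads`` exactly); ``noise="negative_binomial"``
    additionally overdisperses each window count with the given dispersion
    (variance = mean + dispersion * mean^2).
    """

    n_reads: int = 1_000_000
    window: int = 1_000
    noise: Literal["poisson", "negative_binomial"] = "poisson"
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _window_grid(length: int, window: int) -> Tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, window, dtype=np.int64)
    ends = np.minimum(starts + window, length)
    return starts, ends


def expected_coverage(spec: ChromosomeSpec, window: int = 1_000) -> WindowedCoverage:
    """Noiseless coverage track: the analytic copy number at window midpoints."""
    starts, ends = _window_grid(spec.length, window)
    mid = (starts + ends) / 2.0
    return WindowedCoverage(spec.length, window, expected_copy_number(spec, mid))


def simulate_coverage(spec: ChromosomeSpec, cfg: CoverageSimConfig) -> WindowedCoverage:
    """Draw a windowed coverage track from the replication landscape.

    Window probabilities are proportional to the midpoint copy number times
    the window width (midpoint integral approximation; windows are far
    smaller than the landscape's features).  Counts are converted to mean
    per-base coverage by dividing by window width.
    """
    rng = np.random.default_rng(cfg.seed)
    starts, ends = _window_grid(spec.length, cfg.window)
    widths = (ends - starts).astype(float)
    mid = (starts + ends) / 2.0
    weight = expected_copy_number(spec, mid) * widths
    p = weight / weight.sum()
    counts = rng.multinomial(cfg.n_reads, p).astype(float)
    if cfg.noise == "negative_binomial" and cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        lam = rng.gamma(shape, scale=np.maximum(counts, 0) / shape)
        counts = rng.poisson(lam).astype(float)
    return WindowedCoverage(spec.length, cfg.window, counts / widths)


# ---------------------------------------------------------------------------
# growth curves


@dataclass(frozen=True)
class GrowthSimConfig:
    """Exponential-then-saturating OD600 curve settings.

    Defaults emulate M9-glucose batch culture: inoculation at OD 0.02,
    growth rate 0.7 h^-1, saturation near OD 0.5, a reading every 30 min
    for 15 h, and 2% multiplicative measurement noise.
    """

    od0: float = 0.02
    mu: float = 0.7          # h^-1
    carrying_capacity: float = 0.5
    cadence: float = 30.0    # min
    horizon: float = 900.0   # min
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.od0 < self.carrying_capacity):
            raise ValueError("need 0 < od0 < carrying_capacity")
        if self.cadence <= 0 or self.horizon < 0:
            raise ValueError("cadence must be positive, horizon non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def simulate_growth_curve(cfg: GrowthSimConfig) -> GrowthCurve:
    """OD(t) = min(od0 * exp(mu t), K) sampled every ``cadence`` minutes,
    with multiplicative log-normal noise of coefficient of variation
    ``noise_cv``."""
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.horizon + 1e-9, cfg.cadence)
    od = np.minimum(cfg.od0 * np.exp(cfg.mu * t / 60.0), cfg.carrying_capacity)
    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
        od = od * rng.lognormal(mean=0.0, sigma=sigma, size=t.shape)
    return GrowthCurve(t, od)


# ---------------------------------------------------------------------------
# count matrices


@dataclass(frozen=True)
class PopulationDesign:
    label: str
    relative_fitness: float
    n_replicates: int = 2
    lineage: str = "WT"
    is_ancestor: bool = False


@dataclass(frozen=True)
class ExpressionDesign:
    """Negative-binomial count-matrix design with a fitness-scaled shift.

    A random subset of ``round(shifted_fraction * n_genes)`` genes carries
    standard-normal per-gene effects ``delta_g``; a sample of population p
    with relative fitness W_p has mean
    ``s_j * q_g * 2 ** (effect_scale * (W_p - 1) * delta_g)`` on shifted
    genes, where q_g are log-normal baseline means and s_j library-size
    factors drawn log-uniform in [0.5, 2].  The ancestor (W = 1) is
    unshifted, so centroid displacement in expression space grows linearly
    with fitness gain — the structure the dissimilarity regression assumes.

    The default effect scale (2.5) puts a one-sigma shifted gene at
    0.25-1.1 log2 units across fitness gains of 0.10-0.45 — the magnitude
    range of conventionally significant expression changes
    (|fold change| > 1.5 is ~0.585 log2 units) — so the planted divergence
    stands above negative-binomial counting noise the way real adaptive
    expression change does.
    """

    n_genes: int = 2_000
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.05
    populations: Tuple[PopulationDesign, ...] = ()
    shifted_fraction: float = 0.10
    effect_scale: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 <= self.shifted_fraction <= 1):
            raise ValueError("shifted_fraction must be in [0, 1]")
        n_shifted = int(round(self.shifted_fraction * self.n_genes))
        if self.effect_scale > 0 and n_shifted < 1:
            raise ValueError(
                "effect_scale > 0 requires at least one shifted gene"
            )
        for p in self.populations:
            if p.n_replicates < 1:
                raise ValueError("every population needs >= 1 replicate")


def default_expression_design(seed: int = 0, n_replicates: int = 2) -> ExpressionDesign:
    """One-lineage design: an ancestor plus five evolved populations whose
    relative fitness spans the range observed over ~2,000 generations of
    adaptation (1.10-1.45, with 1.16 the triple-origin ancestor's value)."""
    fitnesses = [1.10, 1.16, 1.25, 1.35, 1.45]
    pops = [PopulationDesign("anc", 1.0, n_replicates, "WT", True)]
    pops += [
        PopulationDesign(f"evo{i + 1}", w, n_replicates, "WT", False)
        for i, w in enumerate(fitnesses)
    ]
    return ExpressionDesign(populations=tuple(pops), seed=seed)


def simulate_counts(design: ExpressionDesign) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a gene x sample count matrix and its sample metadata.

    Ground truth for recovery tests rides along: ``counts.attrs`` carries
    the per-gene effects (``"delta"``) and the shifted gene names
    (``"shifted_genes"``); ``meta["true_size_factor"]`` holds each
    sample's library-size scalar.
    """
    if not design.populations:
        raise ValueError("design has no populations")
    rng = np.random.default_rng(design.seed)
    g = design.n_genes
    q = 2.0 ** rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, size=g)
    n_shifted = int(round(design.shifted_fraction * g))
    shifted = rng.choice(g, size=n_shifted, replace=False)
    delta = np.zeros(g)
    delta[shifted] = rng.normal(0.0, 1.0, size=n_shifted)

    genes = [f"gene{i:05d}" for i in range(g)]
    cols, meta_rows = [], []
    data = []
    for pop in design.populations:
        shift = 2.0 ** (design.effect_scale * (pop.relative_fitness - 1.0) * delta)
        for r in range(1, pop.n_replicates + 1):
            s_j = np.exp(rng.uniform(np.log(0.5), np.log(2.0)))
            mu = s_j * q * shift
            if design.dispersion > 0:
                shape = 1.0 / design.dispersion
                lam = rng.gamma(shape, scale=mu / shape)
            else:
                lam = mu
            data.append(rng.poisson(lam))
            sample = f"{pop.label}_r{r}"
            cols.append(sample)
            meta_rows.append(
                {
                    "sample_id": sample,
                    "population": pop.label,
                    "replicate": r,
                    "lineage": pop.lineage,
                    "relative_fitness": pop.relative_fitness,
                    "is_ancestor": pop.is_ancestor,
                    "true_size_factor": s_j,
                }
            )
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    counts.attrs["delta"] = delta
    counts.attrs["shifted_genes"] = [genes[i] for i in sorted(shifted)]
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts, meta


# ---------------------------------------------------------------------------
# writers


def write_growth_tsv(curve: GrowthCurve, path) -> None:
    pd.DataFrame({"time_min": curve.times, "od600": curve.od}).to_csv(
        path, sep="\t", index=False
    )


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")
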