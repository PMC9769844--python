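"""Transcriptome dissimilarity analysis for evolved bacterial populations.

The pipeline: median-of-ratios size factors -> regularized-log-like
transform of normalized counts -> classical (Torgerson) multidimensional
scaling of between-sample Euclidean distances -> per-population centroid
dissimilarity to the lineage ancestor in 3-D MDS space -> linear regression
of dissimilarity on relative fitness.  A lightweight negative-binomial Wald
test with Benjamini-Hochberg correction supplies differential-expression
calls at the conventional thresholds (q < 0.05, |fold change| > 1.5).

Count matrices are pandas DataFrames (genes x samples, non-negative
integers); sample metadata is a DataFrame indexed by sample id with columns
``population``, ``replicate``, ``lineage``, ``relative_fitness`` and
``is_ancestor``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "validate_counts",
    "validate_meta",
    "size_factors",
    "rlog_like",
    "NBWaldDE",
    "de_test",
    "deg_overlap",
    "OverlapReport",
    "ClassicalMDS",
    "classical_mds",
    "MdsEmbedding",
    "centroid_dissimilarity",
    "fitness_regression",
    "RegressionResult",
    "read_counts_tsv",
    "read_meta_tsv",
]

META_COLUMNS = ("population", "replicate", "lineage", "relative_fitness", "is_ancestor")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("gene and sample identifiers must be unique")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    for lineage, sub in meta.groupby("lineage"):
        n_anc = sub.loc[sub["is_ancestor"], "population"].nunique()
        if n_anc != 1:
            raise ValueError(
                f"lineage {lineage!r} must have exactly one ancestor population"
            )
    return meta


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference for gene g is its geometric mean across samples, taken
    over genes with strictly positive counts in every sample; the size
    factor of sample j is the median over those genes of count/reference.
    """
    validate_counts(counts)
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has positive counts in all samples")
    xp = x[all_positive]
    log_ref = np.log(xp).mean(axis=1)
    s = np.exp(np.median(np.log(xp) - log_ref[:, None], axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def rlog_like(counts: pd.DataFrame, s: pd.Series | None = None,
              pseudocount: float = 1.0) -> pd.DataFrame:
    """``log2(count/size_factor + pseudocount)`` per gene and sample.

    A deliberately simple stand-in for a regularized-log transform: its
    contract here is only to supply the sample-space coordinates whose
    Euclidean distances feed MDS.  Genes absent from a strain (deleted
    regions) enter as zero counts and transform to ``log2(pseudocount)``.
    """
    validate_counts(counts)
    if s is None:
        s = size_factors(counts)
    if (np.asarray(s) <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts.div(s, axis=1) + pseudocount)


# ---------------------------------------------------------------------------
# differential expression


class NBWaldDE(BaseEstimator):
    """Two-group negative-binomial Wald test on normalized counts.

    Per gene: normalized group means (pseudocount 0.5 in the log fold
    change), a pooled method-of-moments dispersion with a floor, a
    delta-method standard error of the log2 fold change under the NB
    variance function, a two-sided p value from a t reference with the
    pooled residual degrees of freedom (the small-sample correction needed
    at 2-3 replicates per group, where a normal reference is visibly
    anticonservative), and Benjamini-Hochberg q values.  A gene is a DEG when ``q < alpha`` and the raw
    normalized-mean ratio exceeds ``fc_threshold`` in either direction.

    Genes with zero counts in every sample of both groups are excluded
    before testing and listed in ``excluded_genes_``.
    """

    def __init__(self, alpha: float = 0.05, fc_threshold: float = 1.5,
                 dispersion_floor: float = 0.01, pseudocount: float = 0.5):
        self.alpha = alpha
        self.fc_threshold = fc_threshold
        self.dispersion_floor = dispersion_floor
        self.pseudocount = pseudocount

    def fit(self, counts: pd.DataFrame, meta: pd.DataFrame,
            group_a: str, group_b: str) -> "NBWaldDE":
        validate_counts(counts)
        samples_a = meta.index[meta["population"] == group_a]
        samples_b = meta.index[meta["population"] == group_b]
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValueError("each group needs at least 2 samples")
        sub = counts[list(samples_a) + list(samples_b)]
        s = size_factors(sub)
        norm_counts = sub.div(s, axis=1)
        a = norm_counts[samples_a].to_numpy()
        b = norm_counts[samples_b].to_numpy()

        nonzero = (a.sum(axis=1) + b.sum(axis=1)) > 0
        self.excluded_genes_ = counts.index[~nonzero]
        a, b = a[nonzero], b[nonzero]
        n_a, n_b = a.shape[1], b.shape[1]

        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        var_a = a.var(axis=1, ddof=1)
        var_b = b.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_a = (var_a - mean_a) / mean_a**2
            alpha_b = (var_b - mean_b) / mean_b**2
        alpha_a = np.nan_to_num(alpha_a, nan=0.0, posinf=0.0, neginf=0.0)
        alpha_b = np.nan_to_num(alpha_b, nan=0.0, posinf=0.0, neginf=0.0)
        disp = ((n_a - 1) * alpha_a + (n_b - 1) * alpha_b) / (n_a + n_b - 2)
        disp = np.maximum(disp, self.dispersion_floor)

        ps = self.pseudocount
        ma, mb = mean_a + ps, mean_b + ps
        log2fc = np.log2(mb / ma)
        var_ma = (ma + disp * ma**2) / n_a
        var_mb = (mb + disp * mb**2) / n_b
        se = np.sqrt(var_ma / ma**2 + var_mb / mb**2) / np.log(2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = log2fc / se
        p = 2.0 * t_dist.sf(np.abs(z), df=n_a + n_b - 2)
        q = multipletests(p, method="fdr_bh")[1]

        with np.errstate(divide="ignore", invalid="ignore"):
            fc_raw = mean_b / mean_a
        big = (fc_raw > self.fc_threshold) | (fc_raw < 1.0 / self.fc_threshold)
        big |= np.isnan(fc_raw) & (mean_b > 0)  # something/0 in either direction
        is_deg = (q < self.alpha) & big
        direction = np.where(~is_deg, "none", np.where(log2fc > 0, "up", "down"))

        self.results_ = pd.DataFrame(
            {
                "base_mean_a": mean_a,
                "base_mean_b": mean_b,
                "log2_fold_change": log2fc,
                "dispersion": disp,
                "p_value": p,
                "q_value": q,
                "is_deg": is_deg,
                "direction": direction,
            },
            index=counts.index[nonzero],
        )
        return self


def de_test(counts: pd.DataFrame, meta: pd.DataFrame, group_a: str,
            group_b: str, **kwargs) -> pd.DataFrame:
    """Per-gene DE table for ``group_b`` vs ``group_a``; see :class:`NBWaldDE`."""
    return NBWaldDE(**kwargs).fit(counts, meta, group_a, group_b).results_


@dataclass
class OverlapReport:
    """UpSet-style exclusive intersection counts for up/down DEG sets."""

    up_exclusive: Dict[Tuple[str, ...], int]
    down_exclusive: Dict[Tuple[str, ...], int]
    common_up: Set[str]
    common_down: Set[str]
    common_up_pct: float
    common_down_pct: float


def _exclusive_counts(sets: Mapping[str, Set[str]]) -> Dict[Tuple[str, ...], int]:
    names = list(sets)
    out: Dict[Tuple[str, ...], int] = {}
    universe = set().union(*sets.values()) if sets else set()
    for gene in universe:
        members = tuple(n for n in names if gene in sets[n])
        out[members] = out.get(members, 0) + 1
    return out


def deg_overlap(
    deg_sets: Mapping[str, Tuple[Set[str], Set[str]]]
) -> OverlapReport:
    """Intersection structure of per-population up/down DEG sets.

    The "common" fraction is the size of the intersection over the size of
    the union of the per-population sets, in percent — the statistic used
    to summarize how much of the response is shared across parallel
    populations.
    """
    ups = {k: set(v[0]) for k, v in deg_sets.items()}
    downs = {k: set(v[1]) for k, v in deg_sets.items()}

    def _common(sets: Mapping[str, Set[str]]) -> Tuple[Set[str], float]:
        union = set().union(*sets.values())
        inter = set.intersection(*sets.values()) if sets else set()
        pct = 100.0 * len(inter) / len(union) if union else 0.0
        return inter, pct

    common_up, up_pct = _common(ups)
    common_down, down_pct = _common(downs)
    return OverlapReport(
        up_exclusive=_exclusive_counts(ups),
        down_exclusive=_exclusive_counts(downs),
        common_up=common_up,
        common_down=common_down,
        common_up_pct=up_pct,
        common_down_pct=down_pct,
    )


# ---------------------------------------------------------------------------
# classical MDS and dissimilarity


@dataclass
class MdsEmbedding:
    """Sample coordinates from classical MDS plus the eigenvalue spectrum."""

    coordinates: pd.DataFrame  # samples x dimensions
    eigenvalues: np.ndarray    # non-increasing, full spectrum
    truncated: bool = False    # True when fewer positive eigenvalues than asked

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


class ClassicalMDS(BaseEstimator, TransformerMixin):
    """Torgerson classical multidimensional scaling.

    Double-centers the squared Euclidean distance matrix,
    ``B = -0.5 * J D^2 J``, and embeds samples on the eigenvectors of B
    scaled by the square roots of the leading positive eigenvalues.  For
    distances that are exactly Euclidean in ``<= n_components`` dimensions
    the embedding reproduces them to numerical precision.

    Attributes
    ----------
    embedding_ : ndarray (n_samples, m)
    eigenvalues_ : ndarray, full non-increasing spectrum of B
    truncated_ : bool, True when fewer than ``n_components`` positive
        eigenvalues were available (the embedding is then lower-dimensional).
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None) -> "ClassicalMDS":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.n_components + 1:
            raise ValueError("need at least n_components + 1 samples")
        d2 = squareform(pdist(X, metric="sqeuclidean"))
        n = d2.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * J @ d2 @ J
        evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        tol = max(1e-12, 1e-9 * abs(evals[0])) if evals.size else 0.0
        positive = evals > tol
        m = min(self.n_components, int(positive.sum()))
        self.truncated_ = m < self.n_components
        if self.truncated_:
            warnings.warn(
                f"only {m} positive eigenvalues; returning a {m}-D embedding",
                stacklevel=2,
            )
        self.eigenvalues_ = evals
        self.embedding_ = evecs[:, :m] * np.sqrt(evals[:m])
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


def classical_mds(y: pd.DataFrame | np.ndarray, m: int = 3) -> MdsEmbedding:
    """Embed samples (rows of ``y``) in ``m`` dimensions by classical MDS."""
    est = ClassicalMDS(n_components=m).fit(np.asarray(y, dtype=float))
    index = y.index if isinstance(y, pd.DataFrame) else pd.RangeIndex(len(est.embedding_))
    coords = pd.DataFrame(
        est.embedding_, index=index,
        columns=[f"mds{i + 1}" for i in range(est.embedding_.shape[1])],
    )
    return MdsEmbedding(coords, est.eigenvalues_, est.truncated_)


def centroid_dissimilarity(embedding: MdsEmbedding, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-population Euclidean distance to the lineage ancestor's centroid.

    Each population's centroid is the mean coordinate of its replicates in
    the MDS embedding; its dissimilarity is the distance from that centroid
    to the centroid of the ancestor population of the same lineage.  The
    ancestor's own dissimilarity is zero by construction.
    """
    validate_meta(meta)
    coords = embedding.coordinates
    if not set(coords.index) <= set(meta.index):
        raise ValueError("embedding contains samples absent from metadata")
    meta = meta.loc[coords.index]
    centroids = coords.groupby(meta["population"]).mean()
    pop_info = meta.drop_duplicates("population").set_index("population")
    rows = []
    for pop, row in pop_info.iterrows():
        anc_mask = (pop_info["lineage"] == row["lineage"]) & pop_info["is_ancestor"]
        if not anc_mask.any():
            raise ValueError(f"lineage {row['lineage']!r} has no ancestor")
        anc = anc_mask.idxmax()
        d = float(np.linalg.norm(centroids.loc[pop] - centroids.loc[anc]))
        rows.append(
            {
                "population": pop,
                "lineage": row["lineage"],
                "relative_fitness": float(row["relative_fitness"]),
                "is_ancestor": bool(row["is_ancestor"]),
                "dissimilarity": d,
            }
        )
    return pd.DataFrame(rows).set_index("population")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fitness_regression(points: pd.DataFrame,
                       include_ancestors: bool = True) -> RegressionResult:
    """OLS of transcriptome dissimilarity on relative fitness.

    ``points`` is the frame returned by :func:`centroid_dissimilarity`.
    The p value is the F test of the slope (equivalently the two-sided t
    test in simple regression).  Ancestors enter at dissimilarity zero
    unless ``include_ancestors`` is False.
    """
    df = points if include_ancestors else points[~points["is_ancestor"]]
    x = df["relative_fitness"].to_numpy(dtype=float)
    y = df["dissimilarity"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("relative fitness has zero variance")
    res = linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# plain-text adapters


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes-in-rows count matrix TSV with a header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_counts(df)


def read_meta_tsv(path) -> pd.DataFrame:
    """Sample metadata TSV indexed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "is_ancestor" in df.columns:
        df["is_ancestor"] = df["is_ancestor"].astype(bool)
    return validate_meta(df)
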