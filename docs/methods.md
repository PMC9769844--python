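# Methods

`oriscope` analyzes experimentally evolved *E. coli* populations that carry
one or three chromosomal replication origins: it derives replication-rate
indices from windowed sequencing coverage, growth rates and relative
fitness from OD600 curves, transcriptome dissimilarity from count
matrices, and mutation summaries from populational variant tables. A
synthetic-data module generates all four data types with the statistical
structure the analysis assumes, so every stage can be validated without
sequencing data.

## Replication landscape model

The generator's chromosome model assumes synchronous firing of all
origins, constant and equal fork speed `v` (bp/min), and fork annihilation
where converging forks meet. The replication time of locus `x` is then

    t(x) = min_j  d(o_j, x) / v

where `d` is the shorter circular arc to origin `o_j`; `t` is zero at
every origin, continuous and piecewise linear, and maximal at the midpoint
(in time) of the largest inter-origin gap, `C = max_x t(x)`.

In a steady-state exponential culture with doubling time `tau` (min) the
relative copy number of a locus follows the Cooper–Helmstetter relation

    c(x) = m(x) * 2^((C - t(x)) / tau),

so `c(ori)/c(ter) = 2^(C/tau)`. `m(x)` is an optional segmental
duplication multiplier, applied after the kinetic term: duplication is
modelled as a copy-number effect, not as altered fork kinetics.
Asynchronous firing, cell-age structure beyond the steady-state formula,
and replication–transcription conflict are deliberately outside the model.

Coverage simulation distributes `n_reads` multinomially over windows with
probability proportional to the midpoint copy number times the window
width (midpoint integration; with 1,000-bp windows on a multi-megabase
landscape the quadrature error is negligible). The negative-binomial mode
then overdisperses each window count (variance = mean + α·mean²) via a
gamma–Poisson mixture. In multinomial (Poisson) mode the total read count
is conserved exactly.

Defaults emulate *E. coli* K-12 MG1655: genome 4,641,652 bp, oriC near
3,925,744 bp, fork speed 58,000 bp/min (~1 kb/s replisome speed), doubling
time 40 min. The triple-origin constructor adds origins at 365,000 bp
(lacZ) and 1,240,000 bp (dadX/cvrA), the two insertion loci of the extra
oriC-mioC copies. These kinetic defaults are illustrative of fast growth
in minimal medium, not calibrated measurements for any particular strain.

## Replication indices

Coverage is normalized by dividing each window's mean coverage by the
total over windows ("total coverage" is read as the sum of per-window
means; any constant denominator only rescales the profile uniformly, and
this choice makes the normalized profile sum to 1 — a testable invariant
that preserves all between-window ratios).

**LOESS.** Local polynomial regression with tricube weights over the
`ceil(span·n)` nearest windows, local degree 2, gaussian (non-robust)
fitting, no robustness iterations — the default behaviour of the
conventional statistical environment for this analysis, and verified in
the test suite against R's `loess(..., surface="direct")` to ~7
significant figures. Default span 0.3. Coordinates are treated linearly by
default (matching per-chromosome landscape plots); `circular=True` wraps
half a neighbourhood from each end and is recommended whenever a peak or
trough sits near the coordinate origin. On an evenly spaced grid interior
points share one equivalent kernel, so the fit is computed by convolution;
the kernel path and the generic per-point weighted-least-squares path are
numerically identical and tested against each other.

**Bandwidth resolution rule.** A local-regression bandwidth wider than
the spacing of adjacent origins blurs neighbouring peaks: at span 0.3 on a
4.6-Mb genome the 1.38-Mb neighbourhood exceeds the 875-kb arc between the
two extra origins, displacing the fitted peak by tens of kb and biasing
the multi-origin index several percent low. `resolved_span()` therefore
caps the span at 0.8 times the smallest inter-origin arc (as a genome
fraction) for multi-origin profiles, never above the conventional 0.3.

**Indices.**

- `ptr_loess`: LOESS maximum over LOESS minimum — the ori/ter copy ratio,
  estimating `2^(C/tau)`.
- `multi_ori_index`: sum of LOESS values at the k peak loci divided by the
  value at the terminus locus (default: the global LOESS minimum). On a
  flat profile it equals k, not 1 — the index is k-anchored by
  construction. For wild-type profiles compared against triple-origin
  strains, the convention is pseudo-peaks at 365,000 and 1,240,000 bp plus
  the global maximum.
- `irep_like`: sort log2 normalized coverage, drop the lowest and highest
  5% of windows, regress on rank fraction (ranks from the untrimmed
  ordering, so the slope estimates the full ori-to-ter range), return
  `2^slope`.
- `bptr`: median-filter the profile over 10-kb windows (circular wrap),
  take the ratio of median raw coverage within ±10 kb of the filtered
  maximum and minimum.

Argmax/argmin ties break to the smallest genomic position throughout.

**Duplication detection.** Residual ratio `r_i = c_i / fitted_i` against a
LOESS baseline refitted once on the rank-trimmed profile (windows above
the 95th percentile of first-pass `r` excluded), so a duplicated segment
cannot inflate its own baseline; one refit is the minimal bias
correction, and the trim quantile tolerates duplications covering up to
~5% of the genome. Windows whose 20-window rolling median of `r` reaches
1.7 are flagged; maximal runs of at least 50 kb become calls with the mean
ratio and first/last-window boundaries. All thresholds are exposed.
Because profiles are normalized, a globally doubled library produces no
call. Duplicated segments distort every replication index, which is why a
population carrying one is conventionally excluded from replication-rate
comparisons.

## Growth and fitness

Growth rate is the maximum slope of a sliding 5-point ordinary
least-squares fit of ln(OD) on time, restricted to windows with all OD
above a floor of 0.01 (blank/noise region) and fit R² ≥ 0.99; if no window
qualifies, the best-R² window's slope is returned with a warning flag.
Window length, R² threshold and floor are exposed — the published
analyses used an external tool whose settings are not recorded, so these
are documented stand-in choices. Relative fitness divides a population's
rate by the wild-type ancestor's rate from the same batch. Generations per
serial-transfer cycle are `log2(OD_final / OD_initial)`, summed across
cycles for cumulative generations.

Fitness trajectories are constrained to be non-decreasing: values are
first projected onto the nearest monotone sequence by isotonic regression
(pool-adjacent-violators), then interpolated by the monotone
piecewise-cubic Hermite interpolant (PCHIP) through the projected knots.
A shape-preserving quadratic spline would satisfy the same contract; PCHIP
was chosen because it is the standard shape-preserving interpolant with a
robust implementation, and only monotonicity plus exact interpolation of
the projected knots are contractual. Extrapolation beyond the knot range
is held flat.

## Transcriptome dissimilarity

Size factors are median-of-ratios: reference = per-gene geometric mean
over samples (genes positive in every sample only), size factor = median
ratio to the reference, reported unrescaled. The regularized-log-like
transform is `log2(count/size_factor + 1)` — deliberately simpler than a
full variance-stabilizing fit; its only contract here is to supply sample
coordinates whose Euclidean distances feed MDS. Genes deleted in a strain
are carried as zero counts.

Classical (Torgerson) MDS double-centers the squared distance matrix,
`B = -1/2 · J D² J`, takes the symmetric eigendecomposition, and scales
eigenvectors by the square roots of the leading positive eigenvalues. For
distances that are Euclidean in ≤ m dimensions the embedding is exact;
with fewer positive eigenvalues than requested the embedding is truncated
with a warning. Eigenvector sign and tie order are indeterminate, so all
tests compare distances, never raw coordinates.

Each population's transcriptome dissimilarity is the Euclidean distance in
3-D MDS space between the centroid of its replicates and the centroid of
the ancestor of its own lineage (wild-type populations against the
wild-type ancestor, triple-origin populations against theirs); an
ancestor's own dissimilarity is zero by construction. The
dissimilarity-versus-relative-fitness relation is summarized by ordinary
least squares with dissimilarity as the response (R² is
orientation-invariant in simple regression; the orientation is a
documented choice), p from the F test of the slope. Whether ancestors
(at dissimilarity 0) enter the regression is a flag, default included.

**Differential expression.** A lightweight two-group negative-binomial
Wald test: normalized group means (pseudocount 0.5 in the log fold
change), per-gene method-of-moments dispersion pooled across the two
groups with a floor of 0.01, delta-method standard error of the log2 fold
change under the NB variance function, and a two-sided p value from a t
reference with the pooled residual degrees of freedom. The t reference is
a deliberate small-sample correction: at 3 + 3 replicates the dispersion
estimate carries only 4 degrees of freedom, and a normal reference is
measurably anticonservative (null false-positive rate ~0.085 at nominal
0.05, versus ~0.02–0.03 with the t reference). Benjamini–Hochberg q
values are computed over all tested genes; genes with zero counts in every
sample of both groups are excluded beforehand and reported separately. A
gene is called differentially expressed at the conventional thresholds
q < 0.05 and |fold change| > 1.5, applied to the raw normalized-mean
ratio. DEG overlap across parallel populations is reported as UpSet-style
exclusive intersection counts plus the common fraction
|intersection| / |union| in percent, separately for up- and downregulated
sets.

## Synthetic expression design

Counts are negative binomial with log-normal baseline means (log2 mean 6,
log2 sd 2 — spanning the typical bulk RNA-seq dynamic range), dispersion
0.05, and per-sample library-size factors drawn log-uniform in [0.5, 2].
A fraction f = 0.1 of genes receives standard-normal effects δ_g; a sample
in population p with relative fitness W_p has mean
`s_j · q_g · 2^(κ·(W_p − 1)·δ_g)` on shifted genes. Because all
populations shift along the same direction δ scaled by their fitness gain,
expression-space centroids are collinear and centroid dissimilarity grows
linearly in W − 1 — the simplest mechanism producing a
dissimilarity–fitness line. The effect scale κ = 2.5 places a one-sigma
shifted gene at 0.25–1.1 log2 units across fitness gains of 0.10–0.45,
i.e. the magnitude range of conventionally significant expression changes,
so the planted divergence stands above counting noise the way real
adaptive expression change does. The default population panel is one
ancestor (W = 1) plus five evolved populations at W ∈ {1.10, 1.16, 1.25,
1.35, 1.45}, two replicates each — the span of fitness gains observed
over roughly 2,000 generations of adaptation, with 1.16 the relative
fitness of the faster triple-origin ancestor.

What the generator does **not** emulate: operon and regulon correlation
structure (genes shift independently), mean-dependent dispersion trends,
batch effects beyond a scalar library size, compositional effects of
highly expressed genes, and genuine biological replicate heterogeneity.
Passing recovery tests therefore demonstrates that the pipeline's
statistics are correct and well calibrated under the assumed model, not
that real data will reach any particular R².

## Variant summaries

Variant tables are breseq-style TSVs (lineage, gene, annotation, mutation,
allele frequency in percent, description). Single-base substitutions are
SNPs; deletions, insertions and mobile-element events are DIPs. Codon
changes are parsed from annotations of the form `R69H (CGC→CAC)` and
classified with the standard genetic code: same amino acid → synonymous,
change to a stop → nonsense, any other change → missense; classification
uses only the printed codon pair (no genome-coordinate re-derivation).
Published thresholds mix "over X%" with tables that include boundary
values, so the allele-frequency filter's comparison mode is explicit
(default ≥, strict > available). "Fixed" means allele frequency exactly
100 as printed; no clonality modelling is attempted. The bundled fixture
transcribes the published table of mutations at ≥50% allele frequency in
six evolved lineages (23 records, 17 fixed, 3 nonsense).

## Problem sizes and numerical choices

Simulated genomes are 4.6 Mb at 1,000-bp windows (4,600 windows) with
10⁶ reads per track — deep enough that index noise is a few percent, the
regime where cross-estimator concordance is informative. The
dissimilarity recovery suite uses 20 seeds of 2,000-gene × 12-sample
matrices; the DE calibration suite 2,000 genes at 3 + 3 replicates. All
simulation randomness flows from one explicit integer seed per call (no
global state), and identical seeds reproduce byte-identical outputs.
Degenerate inputs (all-zero coverage, non-positive troughs, empty variant
lists, zero-variance predictors, lineages without an ancestor) raise
errors rather than returning silent defaults.

## Known limitations

- The rlog-like transform is not a variance-stabilizing fit; distances
  between low-count samples are noisier than under a true regularized log.
- The Wald DE test has no dispersion shrinkage across genes; at two
  replicates per group its power is limited, and the dispersion floor
  dominates for high-count genes.
- The iRep- and bPTR-like indices are simplified re-implementations of
  the published pipeline's ideas (sorted-coverage slope; filtered
  peak-to-trough ratio), not reproductions of its filtering heuristics.
- Replication indices assume a steady-state exponential culture; they are
  biased for populations leaving exponential phase or carrying unmodelled
  structural variation.
- The duplication scanner reports rectangular calls only; nested or
  partial-copy events are summarized by their mean ratio.
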