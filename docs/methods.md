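# Methods

This note documents the models, estimators and numerical choices behind
swathbench: what each pipeline stage computes, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Data model

An `IntensityTable` is a protein × sample real matrix with unique row and
column ids and a group label per sample. Missing cells are NaN in the
value matrix; the missing mask is derived from that encoding, so a
missing cell can never carry a stale value. Raw matrices are
nonnegative-or-missing; after transformation values may be any real.
Every chain stage maps a table to a table of the same shape and never
mutates its input. The pipeline is feature-agnostic: any feature ×
sample matrix (protein- or peptide-level) is acceptable.

## Analysis chains

A chain is the ordered triple transformation → normalization →
imputation. The order is fixed: statistics in stages 1–2 are computed on
observed cells only and missing cells pass through untouched until stage
3 resolves (or, for `NON` imputation, keeps) them. The full registry is
4+1 × 15+1 × 6+1 = 560 chains; enumeration is the Cartesian product in
lexicographic code order. Stage errors (domain violations, degenerate
scale statistics, insufficient overlap/data, non-convergence) are caught
and recorded as structured failures — a failed chain-dataset pair never
aborts a sweep. Sweeps cache shared transformation and
transformation+normalization prefixes per dataset; the cached sweep is
bit-identical to running each chain independently because all per-method
randomness is seeded from (base seed, dataset id, stage codes) alone.

## Transformations

* `LOG`: log base 2 (configurable); requires positive observed values.
* `CUB`: real cube root, defined for all reals.
* `POW`: x^e with e = 0.5 by default, e ∈ (0,1); nonnegative inputs
  required (0 is allowed). The square root is the canonical
  variance-stabilizing power transform for count-like intensities; the
  exponent is configurable because the literature is not specific.
* `BOX`: one-parameter Box-Cox, λ estimated once per matrix by maximum
  likelihood on all pooled observed values (per-sample λ would confound
  the downstream normalization comparison); positive inputs required.

All are strictly monotone on their domain and leave the mask unchanged.

## Normalizations

Per-sample location/scale (statistics over observed cells of a column;
grand statistics over all observed cells): `MEA` x·(grand mean / column
mean), `MED` x·(grand median / column median), `TIC` x·(mean column sum /
column sum), `ZSC` (x − column mean)/column sd (ddof 1), `MAD` (x −
column median)/column MAD (no consistency constant). Per-protein scaling:
`AUT` (x − row mean)/row sd, `PAR` (x − row mean)/√(row sd); rows with
< 2 observations or zero spread carry no scale information and are
emitted as missing rather than failing the chain.

`PQN`: TIC pre-scaling, then each column divided by the median over
proteins of x_ij / reference_i, reference = per-protein median across
samples. `QUA`: each column's quantile function is interpolated to a
common grid of the maximum column length and replaced by the across-
column mean quantile function; for complete matrices this reduces exactly
to classic rank-mean quantile normalization, and tied values receive the
mean of the means over their tied ranks.

`TMM`: reference sample = column whose upper quartile is closest to the
mean upper quartile; M = log2 ratios and A = mean log2 abundances over
proteins observed (and strictly positive) in both sample and reference;
the top/bottom 30% of M and 5% of A are dropped; the factor is 2 to the
precision-weighted mean of the remaining M (delta-method weights
1/(1/x_j + 1/x_ref)), factors rescaled to multiply to 1 and applied as
division. Nonpositive cells are excluded from the M/A pairs the way zero
counts are in the count-based original; fewer than 10 usable pairs is an
insufficient-overlap failure.

`LOW`/`RLR`: per sample, the difference d to the per-protein median
reference is modeled as a function of the mean level A and the fitted
trend subtracted — by loess (span 0.7) for `LOW`, by a straight line fit
with iteratively reweighted least squares under Huber weights (tuning
constant 1.345, MAD scale) for `RLR`. `CYC`: for every unordered sample
pair, loess of M on A; half the trend subtracted from one sample, added
to the other; 3 cycles. Pairs sharing fewer than 10 co-observed proteins
are skipped.

`VSN`: per-sample affine calibration followed by arsinh (generalized
log): h_j(x) = arsinh(a_j + b_j·x), b_j > 0. The coefficients minimize
the pooled deviation from the per-protein median reference by trimmed
least squares over the middle 90% of proteins, iterating the trim set
until the largest coefficient change falls below `vsn_tol`. The
deviation criterion alone is unidentified in overall scale (b → 0
collapses it), so the reference is held fixed at the raw per-protein
median, which anchors the scale; with that anchor the iteration
converges in a few passes, and non-convergence is flagged with a
warning, never a chain failure.

`EIG` (EigenMS-style): per-protein group means are removed, the residual
matrix of complete-case proteins is decomposed by SVD, and the number of
significant bias trends is the count of leading singular values
exceeding the (1−α) quantile of the first singular value under random
permutations of the residuals — permuted within rows *within each
group's columns*, because group centering imposes a per-row zero-sum
constraint per group and a global permutation would break it, deflating
the null and roughly quadrupling the false-trend rate at α = 0.05.
Significant trends (right singular vectors) are projected out of every
protein's observed residuals and the group means re-added, so group-mean
differences are preserved exactly. Complete-case proteins fewer than the
sample count is an insufficient-data failure — on wide matrices with
realistic missingness this is the dominant failure mode of the sweep.

## Imputations

`ZER` missing ← 0. `BAK` missing ← the 1st-percentile (configurable) of
the sample's observed values. `CEN` missing ← half the protein's minimum
observed value (half the matrix minimum for fully missing proteins) — the
simplest deterministic member of the left-censored imputation family.
`KNN`: neighbors are protein rows; distance = √(mean squared difference
over co-observed samples) (count-normalized so unequal overlaps are
comparable; ≥ 2 shared samples required); the k = 10 nearest donate a
1/distance-weighted average in each missing sample, zero distances
getting equal weights; donors missing in that sample are skipped, with
the protein's own observed mean as last resort. `SVD`: iterative
completion — initialize missing cells with row means, alternate rank-r
(r = 5) truncated SVD reconstruction with overwriting of missing cells
only, until the RMS change on missing cells < 1e-4 or 100 iterations;
growth of the change by 10× over 5 consecutive iterations is a
divergence failure. `BPC`: EM for probabilistic PCA with automatic-
relevance-determination priors on component scales; weights initialized
from the SVD of the row-mean-filled matrix (random starts leave
components mixed for hundreds of iterations, the SVD start is
deterministic and lets ARD shrink superfluous components within tens);
the effective rank is the number of components whose scale exceeds 10⁻³
of the largest. ARPACK-based truncated SVDs use a fixed start vector so
that every sweep is bit-reproducible.

All imputation methods leave observed cells bit-identical and (except
`NON`) return a complete matrix.

## Precision assessment

PMAD as defined in the README: per-group per-protein MADs over observed
replicates (≥ 2 required), averaged over eligible proteins within group,
then over groups. Groups left with no eligible protein are dropped from
the outer mean; a table where every group is empty is an assessment
failure. No consistency constant and no back-transformation: each chain
is scored on its own output scale, so chains on different measurement
scales share one PMAD axis — exactly the comparison the benchmark makes,
with the caveat that cross-scale PMAD comparability is a convention of
this metric, not a theorem. Categories: superior ≤ 0.3 < good ≤ 0.7 <
poor; failed chains are unranked and listed after ranked ones; ties in
ranking break lexicographically by chain label.

## Clustering and CWPACs

Complete performance vectors are Ward-clustered (scipy linkage, Ward
coefficients in the Lance–Williams recurrence under the squared-distance
convention) on log10 PMAD by default: raw PMADs span ~15 orders of
magnitude and raw-space Euclidean distances would be dominated entirely
by the worst chains; raw-space clustering remains available. PMADs are
floored at 1e-18 before log10 so that exact-zero PMADs (attainable on
noise-free synthetic data) stay finite. The k-way cut (default 6) names
partitions A1, A2, A3, B, C, D by ascending mean log10 PMAD. CWPAC flags:
*strict* = PMAD ≤ 0.7 on every dataset; *partition-based* = membership in
a partition where ≥ 90% of member PMADs meet the cutoff (both
thresholds configurable). The heatmap export clamps log10 PMAD to [−5, 5]
for a symmetric color scale; the dendrogram exports as Newick with chain
labels.

## Synthetic data

The generator draws log-normal protein abundances (natural-log mean 14,
sd 2 — intensities around 10⁶ spanning several decades), a log-uniform
per-sample scale bias on [0.5, 2] (total-ion-current variation), additive
Gaussian noise on the log scale (sd 0.1), a 10% fraction of proteins
with a ln 2 between-group shift, and missingness = MCAR floor (2%) plus
logistic left-censoring in log intensity (steepness 1.5, midpoint 11,
i.e. the low-abundance tail), giving ~10% missing cells overall. The
default benchmark suite mirrors the replicate structure of published
two-group SWATH benchmark studies: group sizes (3,3), (6,6), (10,10),
(18,18), (18,18), (20,20), (72,44) — total sample counts 6 to 116.

What the generator does *not* emulate: peptide-to-protein roll-up,
retention-time drift, interferences, batch structure beyond a single
rank-1 bias, or heavy-tailed contamination. Passing tests therefore
demonstrate correct implementations and the expected qualitative
ordering of chains under scaling bias + left-censoring — not that any
particular chain is optimal for a given real instrument run.

## Problem sizes and numerical choices

The full-scale end-to-end check sweeps 560 chains × 7 datasets at 1,000
proteins (≈ 5–7 minutes on one CPU) with low-rank imputation capped at
30 iterations; the package defaults (100) suit single-dataset use. Loess
fits use the statsmodels lowess delta shortcut (1% of the A-range) and,
above 400 points, a rank-spread 400-point subsample with linear
interpolation — pairwise cyclic loess is O(s²) fits per iteration and
this keeps the 116-sample dataset tractable without materially changing
the fitted trends. Ward linkage is validated against an exhaustive
O(n⁴) re-implementation that recomputes the within-cluster variance
increase for every candidate merge. All randomness flows from a single
base seed fanned out by CRC32 of (dataset id, stage codes), so serial,
parallel and re-run sweeps are bit-identical.

## Known limitations

* PMAD is a precision-only criterion: a chain that compresses all values
  toward a constant scores well regardless of accuracy (quantile
  normalization of two samples is the degenerate extreme). Accuracy- or
  differential-expression-based assessment is out of scope by design.
* The VSN estimator is the simplified robust affine+arsinh calibration,
  not the original maximum-likelihood formulation with shrinkage.
* EigenMS requires complete-case proteins ≥ samples, which realistic
  missingness rarely satisfies on wide matrices; those chains fail
  honestly rather than imputing before normalization.
* The "Power" transformation's exponent and the Box-Cox λ sharing are
  package conventions (0.5; one λ per matrix) where the literature is
  silent.
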