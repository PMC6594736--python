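# Methods

This note documents the models and procedures `asgroups` implements, the
parameters that matter, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Data model and preprocessing

An `OTUTable` is an integer matrix with one row per OTU and one column per
sample (the classic QIIME orientation), validated for non-negative integer
counts and unique identifiers, with optional semicolon-delimited taxonomy
per OTU and key/value metadata per sample. Classic TSV is the primary
format; dense BIOM-style JSON is accepted read-only. Output TSVs are written
with deterministic column order and floats at six significant digits.

**Rarefaction** normalizes read depth by a single seeded
multivariate-hypergeometric draw per sample (subsampling without
replacement, the behaviour of standard single-rarefaction tools). Samples
below the target depth are dropped with a warning — subsampling cannot
create reads — and OTU rows that become all-zero are kept by default so that
group labels remain addressable (`drop_empty=True` removes them). An
averaged-rarefaction option (`n_draws > 1`) exists but the default is one
draw. Typical depths in multi-plant sludge surveys are 7,000 reads per
sample for bacteria and 12,000 for archaea; 7,000 is the package default.

**Hellinger transformation** (square root of per-sample relative
abundances) is applied before ordination and the location-effect tests, so
Euclidean-geometry methods behave sensibly on count data. The β-null
analysis deliberately works on raw rarefied counts instead, because its
null model generates counts (see below).

## Core–satellite partition

For each OTU the counts across the *n* samples yield the mean x̄, unbiased
sample variance s² (zeros included), and occupancy (samples with count
> 0). Two dispersion statistics are available:

* `paper` (default): D = (s² / x̄) · occupancy;
* `classic`: D = (n − 1) · s² / x̄, the textbook Poisson dispersion
  statistic, whose null distribution is exactly χ² with n − 1 degrees of
  freedom.

Both are compared with the 2.5% and 97.5% quantiles of χ²ₙ₋₁. The default
statistic is the one used in the sludge-survey literature this package
follows; it has no exact χ² null (the occupancy factor replaces n − 1), so
the `classic` mode is provided for calibrated inference, and the test suite
verifies its 5% nominal type-I error on i.i.d. Poisson tables. No claim is
made that either mode reproduces any specific published OTU count.

Labels: over-dispersed (D above the upper quantile) **and** occupying at
least half the samples → core; over-dispersed but restricted, or inside the
band (randomly placed) → satellite; under-dispersed or all-zero →
unclassified. The occupancy requirement (configurable,
`core_min_occupancy_frac=0.5`) prevents an OTU confined to one sample —
maximally aggregated, hence strongly over-dispersed — from being called
"widely distributed". Published surveys show a large unclassified remainder,
which is why under-dispersed OTUs are not folded into satellite.

## Generalist–specialist partition

The null model is **fixed–fixed with fill**: each of `n_null` (default
1,000) null tables preserves every OTU's total reads, every sample's depth,
and the total number of occupied cells. Construction: draw a table with the
observed margins from the conditional-uniform distribution (Patefield's
algorithm, via scipy), then repair its fill with margin-preserving 2×2
diagonal transfers — annihilating transfers while the fill is too high, unit
transfers while too low, rejecting moves in the wrong direction — until the
observed fill is reached (the quasiswap scheme). The inner loop is
numba-compiled with a self-contained xorshift64* generator; each null table
gets an independent sub-seed derived from `(seed, table_index)`, so nulls
are reproducible and order-independent. The repair-loop budget is
`100 × n_cells` iterations per table; exceeding it raises an error with the
remaining fill gap rather than returning a biased table.

Per null table the metric is recomputed per OTU: occurrence (default) or
Levins' niche breadth B = 1/Σⱼ pᵢⱼ². The observed metric is compared with
the null's empirical 2.5th/97.5th percentiles (a mean ± 1.96·SD variant is
available, since percentile and normal intervals can differ for the
integer-valued occurrence). Above the upper bound → generalist; below the
lower → specialist; otherwise nonsignificant. Occurrence is the default
metric because it is the quantity the classification is defined on; niche
breadth is offered because the widely used R implementation of this test
(EcolUtils) ranks OTUs by Levins' B.

Group overlaps (the Venn numbers) report shared OTU counts and percentages
of each group's total, rounded to one decimal half-up — the convention used
when comparing with published survey percentages.

## β-null deviation

For one OTU group: restrict the table to the group's rows, compute observed
pairwise Bray–Curtis BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on the rarefied counts,
then for each of `n_null` (default 999) iterations rebuild every sample by
drawing its observed group read total from the regional relative abundances
(group row totals pooled over samples). This preserves local community size
and the regional species-abundance distribution while randomizing
composition — the abundance-based β-diversity null. The expected
dissimilarity of a sample pair is its mean over nulls; the deviation is
observed − expected, reported per pair (so distributions can be plotted and
rank-tested) and as the mean. Samples with zero group reads are excluded
with a warning; a pair of all-zero samples has BC = 0 by convention.

Draws are multinomial (with replacement) by default; `replace=False`
switches to without-replacement draws from the finite pooled reads. At
survey depths the pool is vastly larger than any one sample, so the two
agree to well within null noise (tested).

Deviations near zero mean the observed turnover is indistinguishable from
random sampling of a common pool (stochastic assembly); deviations away
from zero mean systematic turnover (deterministic assembly). Group
contrasts use the two-sided Wilcoxon rank-sum test on the pooled pairwise
deviations, with the sign of the median difference reported; the test
requires both groups to span the same retained sample set and errors
otherwise.

## Permutation statistics

All label-permutation tests share conventions: seeded permutations, the
Monte-Carlo `(count + 1)/(n_perm + 1)` p-value (never zero, bounded below by
1/(n_perm+1)), default `n_perm = 999`, and an `n_perm="exact"` mode that
enumerates all distinct label arrangements and returns the exact p.

* **adonis (one-way PERMANOVA)**: SS_total = Σ_{i<j} d²ᵢⱼ/N; within-group
  sums divided by group size; F = (SS_b/(a−1))/(SS_w/(N−a)); R² =
  SS_b/SS_total; upper-tail permutation p. A zero within-group sum gives
  F = ∞, which compares correctly under the ≥ counting rule.
* **ANOSIM**: R = (mean between-rank − mean within-rank)/(M/2) with
  M = N(N−1)/2; average ranks for ties; upper-tail p.
* **MRPP**: δ = Σ_g (n_g/N) · (mean within-group distance); singleton groups
  contribute zero (logged); lower-tail p (cohesive grouping ⇒ small δ).
* **Mantel**: Pearson or Spearman correlation of upper triangles; one
  matrix's rows/columns permuted simultaneously; one-sided (greater) p, the
  convention of vegan's `mantel`.
* **Wilcoxon rank-sum**: delegated to scipy's Mann–Whitney U (converted to
  the rank-sum statistic); exact enumeration when n₁+n₂ ≤ 12 without ties,
  otherwise normal approximation with continuity correction.
* **PCoA**: Gower double-centering of −½d², symmetric eigendecomposition,
  coordinates scaled by √λ over positive eigenvalues. Negative eigenvalues
  (non-Euclidean dissimilarities such as Bray–Curtis) are reported with a
  warning, not Lingoes/Cailliez-corrected.

The abundance–occupancy relationship is an OLS fit of log₁₀(mean count,
zeros included in the mean) on integer occupancy, over OTUs with nonzero
totals. Taxon composition sums reads per taxon per group, normalizes within
group, and collapses taxa below 0.5% of the group's reads into "Other";
taxa at exactly the threshold are retained (≥, documented boundary rule).

## Synthetic metacommunities

The generator emulates the statistical structure of a multi-plant amplicon
survey, not its biology. Regional relative abundances πᵢ are lognormal
(default σ = 2 on the log scale — strongly uneven, a few dominants over a
long rare tail, which produces the positive abundance–occupancy relationship
seen in real surveys). Defaults: 13 samples, 500 OTUs, 7,000 reads per
sample. Two assembly modes:

* **neutral**: every sample is one multinomial draw of the read depth from
  π — between-sample differences are pure sampling noise;
* **niche**: each OTU receives an optimum μᵢ uniform over the range of a
  one-dimensional environmental axis (default: samples evenly spaced on
  [0, 1]) and sample j draws from probabilities ∝ πᵢ·exp(−(envⱼ−μᵢ)²/2σ²)
  with niche breadth σ = 0.15 by default — narrow enough that turnover along
  the axis dominates.

Read sampling is multinomial (with replacement), the standard amplicon
sampling model; at these depths individual-based draws are indistinguishable.
A single environmental axis is enough to create deterministic structure for
recovery tests even though real covariates (NH₄-N, heavy metals, …) are
multi-dimensional.

`plant_group_structure` appends rows with known labels: core rows are
Poisson counts around a lognormally-varying per-sample intensity (abundant
everywhere, strongly over-dispersed); satellite rows put ~8 reads in 1–2
samples (inside or above the χ² band but restricted); generalist rows put
one read in every sample (occupancy saturates while marginal-preserving
nulls leave gaps, because their total is small); specialist rows concentrate
20 reads in each of two fixed samples (null occurrence far above 2). These
intensities were chosen from the analytic behaviour of the tests (e.g. a
total of ~13 reads leaves the null's 97.5th occupancy percentile below 13)
so that recovery is determined by the machinery, not by tuning.

**What the benchmarks show — and don't.** Passing recovery and calibration
tests demonstrates that the estimators detect the structure they are defined
to detect, under a generative model matched to their assumptions. Real
amplicon data add compositional artefacts, sequencing error, taxa correlated
through interactions, and environmental gradients that are neither 1-D nor
Gaussian; none of these are simulated, so synthetic recovery rates must not
be read as field error rates.

## Pipeline conventions

The pipeline derives one sub-seed per stage as SHA-256 of
`"<master_seed>:<stage_name>"` (truncated below 2³¹), so adding a stage
never perturbs earlier stages' randomness, and reruns with the same
configuration are byte-identical (the manifest records config, stage seeds,
package version and per-output row counts, and deliberately no timestamps).
Stage failures abort with the stage name and leave a manifest flagged
incomplete. YAML config with CLI-flag overrides, precedence CLI > file >
defaults.

In pipeline runs the per-group location tests (adonis/ANOSIM/MRPP) and the
β-null/Wilcoxon contrast between core–satellite and specialist–generalist
pairs are computed when the groups are non-trivial; a comparison whose two
groups retain different sample sets (a group absent from some samples) is
skipped with a note in the manifest rather than computed on mismatched
pairs.

Default problem sizes in the test suite and acceptance script (e.g. 13 × 500
× 7,000 simulations, 99-iteration β-nulls over 20 replicate seeds, 1,000
quasiswap nulls on 150–220-row tables) were chosen as the smallest sizes at
which the sampling noise of each checked quantity is comfortably below its
assertion margin.

## Known limitations

* The `paper`-mode dispersion statistic lacks an exact χ² null; its
  occupancy factor makes it conservative for rare OTUs and liberal for
  widespread ones. Use `classic` mode when calibrated type-I error matters.
* Quasiswap mixing is not proven uniform over the fixed-fixed-fill ensemble;
  like the standard R implementation, it relies on a conditional-uniform
  start plus many local moves. Contract properties (margins, fill) are
  asserted exactly; distributional uniformity is checked only on 2×2 cases.
* The β-null deviation inherits the abundance-based null's known dependence
  on community size and pool definition; comparisons are therefore made
  between groups within the same table, not across tables.
* Incidence-based (Raup–Crick) deviations, phylogenetic nulls (βNTI),
  constrained ordination and spatial eigenfunction analysis are out of
  scope.
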