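# Methods

## Problem setting

A spike-in dilution experiment adds known amounts of synthetic
oligonucleotides (here, plant miRNAs absent from the human genome, feature
ids prefixed `ath-`) to a constant biological background before library
preparation. Because the background is the same RNA in every sample, any
between-sample difference in background counts is technical; the spike-ins,
whose relative amounts differ by known factors, provide positive controls
with exact nominal fold changes. `mirnorm` simulates this design, normalizes
the counts with eight standard methods, and scores each method on variance
reduction, dilution-series bias, and precision–recall of fold-change-based
differential-expression calls.

## Data model and conventions

Counts live in a features × samples matrix (`CountMatrix`); all per-sample
statistics are column statistics. Raw counts are non-negative integers;
normalized matrices may be fractional and refuse integer-only operations
(subsampling). Every log transform in the package uses log2(x + 1): the
pseudocount makes zeros finite at the cost of compressing values of order 1.
Percentiles use linear interpolation between order statistics throughout.

The *baseline* sample is the one with the median library size; with an even
number of samples the lower of the two middle values is taken, and exact
ties break to the lexicographically smallest sample id — deterministic and
independent of column order. Library sizes are computed on the matrix as
given; if low-count filtering is applied first, scaling uses post-filter
totals (the two choices differ by one call-order decision, and keeping each
operation self-contained was preferred).

Low-count filtering keeps features with at least `min_count` (default 5)
reads in at least ceil(`min_fraction` × n_samples) samples (default 25 %,
boundary inclusive). Depth subsampling draws each column without replacement
(multivariate hypergeometric), so subsampled column sums match the target
exactly and no cell grows.

## Normalization methods

1. **cpm** — x′ = x · 10⁶ / s_j. Output columns sum to exactly 10⁶.
2. **Total-count scaling** — d_j = s_baseline / s_j, x′ = d_j · x. Output
   columns sum to the baseline library size.
3. **Upper quartile** — q_j is the 75th percentile of sample j's counts over
   features with nonzero total; factors g/q_j with g the geometric mean of
   the q's, hence geometric-mean-1 factors. Anchoring to the geometric mean
   rather than to one reference sample keeps the method symmetric and
   order-independent.
4. **TMM** — reference sample: the one whose 75th percentile of x/s is
   closest to the mean such percentile. For each sample vs the reference,
   over features positive in both: M = log2 ratio of depth-scaled counts,
   A = average log2 intensity, delta-method variance
   v = (s_k−x_k)/(s_k x_k) + (s_r−x_r)/(s_r x_r). The upper and lower
   trim/2 tails of M (30 % total) and of A (5 % total) are discarded by rank
   (keep floor(n·trim/2)+1 ≤ rank ≤ n+1−floor(n·trim/2), average ranks for
   ties) and the surviving intersection yields
   log2 f = Σ(M/v) / Σ(1/v). Factors are rescaled to geometric mean 1 and
   counts normalized as x′ = x · Ñ/(s f) with Ñ the geometric mean library
   size, so a pure depth change leaves the TMM factor at 1. Degenerate
   cases: no shared positive features or an empty post-trim set give factor
   1 with a warning; a single shared feature determines the factor alone.
5. **Median-of-ratios** — over features positive in every sample, g_i is the
   geometric mean across samples and the size factor is
   s*_j = median_i(x_ij/g_i); x′ = x/s*_j. Note the equivariance is
   relative: scaling one column by c multiplies every g_i by c^(1/n), so
   only factor *ratios* shift by exactly c.
6. **Linear regression** — each sample is compared with a fixed baseline
   profile (per-feature median across samples) on the MA plane; an OLS fit
   M = β0 + β1·A is removed (M′ = M − M̂) and the sample rebuilt as
   x′ = 2^(A + M′/2). Only the sample channel is adjusted so the baseline
   stays common to all samples. Zero-count features pass through unchanged;
   a degenerate A axis (zero spread) falls back to centering M.
7. **Cyclic loess** — on the log2(x+1) scale, for every unordered sample
   pair the lowess smoother c(A) of M on A is estimated over shared positive
   features and half the correction applied with opposite signs to the two
   samples; the cycle over all pairs runs 3 times with span 0.7 (common
   practice for this algorithm; both exposed as parameters). Pairs with
   fewer than 10 shared positive features are skipped with a warning.
   Output returns to the count scale as 2^L − 1, floored at 0.
8. **Quantile** — each value is replaced by the cross-sample mean of the
   values at its rank; tied entries receive the average of the reference
   values over their tied ranks (stable under permutation of tied entries).
   Sorted columns are exactly identical when columns are tie-free; with
   ties, the tie-averaging rule perturbs the affected column's multiset.

The MA average is read as A = ½·log2(x₁·x₂), the standard MA-plot
definition, wherever a ratio/product ambiguity could arise.

## Synthetic spike-in experiment

`make_latin_square_design(n, concentrations)` builds the cyclic design:
sample i, spike-in j receives concentration (i+j) mod n. Each level appears
exactly once per row and column; in particular every sample carries the same
total spike amount, so the spike-ins themselves add no composition
difference.

Background counts: relative abundances are log-normal
(`abundance_log_sd = 2.5`, natural log), giving the strong dominance
structure of real miRNA libraries, where a handful of miRNAs can take 10–25 %
of all reads — this skew is what makes the observed column sum a *noisy and
composition-sensitive* depth estimator, the failure mode that separates
count-sum scaling from the robust estimators. Expected counts are abundance
share × sample depth; observed counts are negative binomial with dispersion
φ (variance μ + φμ², default φ = 0.05, Poisson at φ = 0).

Sequencing depths default to log-uniform in [1 × 10⁵, 5 × 10⁵] expected
reads per sample — deliberate desk-scale stand-ins for the millions of reads
of a real run; every benchmark conclusion is scale-free. Equal depths or an
explicit depth list are available.

Spike-in counts: spike s in sample i has expected count
κ_s · amount_{i,s} · depth_i / mean depth, with one log-normal capture
efficiency κ_s per spike-in (default 10 expected counts per amol at the
reference depth, log-sd 0.5). Because κ_s is shared across samples it moves
only the dilution-series intercept: the true log2(count)–log2(amount) slope
is exactly 1 by construction, so any slope deviation measured downstream is
pipeline bias (plus the +1 pseudocount's compression of the lowest points).
A 0 amol assignment yields exactly zero counts.

Bias scenarios:

* **Composition** — the top `composition_fraction` most-abundant background
  features (default 5 %) are multiplied by `composition_fold` (default 4) in
  the affected samples (default: the second half). Targeting the dominant
  features implements composition bias in its standard sense — a minority of
  highly expressed species consuming sequencing real estate — and inflates
  the affected columns' sums by a factor the count-sum methods mistake for
  depth. Setting fraction 0 or fold 1 is bit-identical to no scenario.
* **Intensity distortion** — counts multiplied by 2^g with
  g = amplitude·sin(0.8·log2(μ+1)), a smooth bounded intensity-dependent
  warp that only the regression-type methods can remove.

The truth table records, for every unordered sample pair, the nominal log2
fold change of every feature: 0 for background, log2 of the amount ratio for
spike-ins. Pairs where exactly one amount is 0 are flagged *infinite*; they
count as true positives in precision–recall but are excluded from
absolute-bias arithmetic, where no finite nominal value exists.

## Evaluation

* **RLE**: log2(x+1) minus the per-feature median across samples, with
  per-sample quartiles for boxplot summaries. A quantile-normalized matrix
  has per-sample median RLE exactly 0.
* **Variance summary**: per-feature variance of log2(x+1) across samples,
  before vs after normalization; `fraction_lower` is the share of background
  features whose variance *strictly* decreased (boundary equality does not
  count).
* **Variance-ratio trend**: log2(var_norm/var_raw) against mean log2
  abundance with a lowess smoother; features with zero raw variance are
  excluded, and fewer than 10 usable features yields points only.
* **Dilution bias model**: per spike-in, OLS of log2(count+1) on
  log2(amount) over samples with amount > 0 (the 0 amol sample is excluded —
  its log amount is undefined). R² is the squared Pearson correlation of
  observed and fitted values. Known problematic series can be excluded by
  id. The paper-style model has no pseudocount; ours adds +1 for
  zero-safety, which flattens slopes measurably when the lowest expected
  counts are of order 1 — tolerances in the tests account for this.
* **Fold changes**: log2((x_j+1)/(x_k+1)) for all pairs or against a chosen
  reference; antisymmetric in orientation.
* **Precision–recall**: thresholds sweep the unique observed |log2 FC|
  values (plus +∞); precision with zero predictions is 1 by convention;
  the area uses step interpolation over recall and equals average precision
  for tie-free scores. Both per-pair curves and a pooled curve over all
  pairs are computed. The pooled curve is the more sensitive instrument:
  a per-pair sweep cannot see a constant per-pair shift, while pooling
  penalizes methods whose normalized scale is inconsistent *between* pairs.
* **Absolute bias**: estimated minus nominal log2 fold change, pooled over
  pairs, summarized by median and quartiles.
* **Concordance**: Spearman correlation matrix of pooled fold-change vectors
  across methods, clustered by complete linkage on Euclidean distances
  between correlation-matrix rows. A constant vector is rejected by method
  name.

## Numerical and design choices

* Matrix orientation is fixed (features in rows); orientation bugs surface
  as shape errors, not silent transposes.
* Downsampling uses exact without-replacement draws rather than binomial
  thinning so column sums match the target exactly.
* The TMM trim rule and reference choice follow the method's standard
  definition (rank-based trimming, intersection of survivors,
  precision weights); an independent brute-force reimplementation of the
  weighted trimmed mean serves as the test oracle.
* Quantile tie handling averages reference values over tied ranks rather
  than interpolating at the mean rank; the two differ for ties spanning
  three or more ranks.
* Seeds: every stochastic component takes an explicit seed or NumPy
  Generator; identical seeds give byte-identical TSV outputs.

## What the simulator does and does not capture

The generator reproduces the statistical skeleton of a spike-in dilution
experiment: known design, constant background, overdispersed counts,
depth variation, composition and intensity bias. It does not model
read-level artifacts (adapter chimeras, ligation sequence preferences,
isomiR redistribution, alignment ambiguity), per-sample correlated
technical effects beyond the two scenario knobs, or the specific abundance
spectrum of any real reference RNA. Passing benchmarks here therefore
demonstrates that each method behaves as its theory predicts under its
intended failure modes — not that the same percentages would be observed on
any particular real data set. The benchmark's problem sizes (500 background
features, 12 samples, 10⁵-scale depths) were chosen so the full suite runs
interactively; all reported comparisons are invariant to that scale choice.

## Known limitations

* The +1 pseudocount couples evaluation metrics to each method's output
  scale (cpm's 10⁶ anchor inflates or deflates counts relative to raw),
  which is visible in low-count fold-change compression; this mirrors the
  standard practice of evaluating on log2(x+1) but should be kept in mind
  when comparing methods whose outputs live on very different scales.
* Median-of-ratios requires at least one feature positive in all samples;
  heavily zero-inflated matrices need filtering first.
* Cyclic loess cost grows quadratically in the number of samples.
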