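# mirnorm

Benchmarking toolkit for **miRNA-seq count normalization** built around a
spike-in dilution design.

Small RNA sequencing yields a matrix of read counts (miRNAs × samples) whose
scale is contaminated by technical effects: sequencing depth, RNA
composition, and intensity-dependent distortions. Many normalization schemes
exist and they disagree; the only way to compare them objectively is on data
where the truth is known. `mirnorm` provides that comparison end to end:

* **Eight normalization methods** — counts-per-million (cpm), total-count
  scaling, upper-quartile (UQ) scaling, trimmed mean of M-values (TMM),
  median-of-ratios size factors, MA-plot linear regression, cyclic loess,
  and quantile normalization — implemented on a common count-matrix
  container with per-sample scaling factors where they exist.
* **A synthetic spike-in experiment generator**: 12 synthetic
  oligonucleotides at 12 known amounts (0, 0.1, 0.2, 0.8, 1.6, 6.4, 12.8,
  51.2, 102.4, 409.6, 819.2, 3276.8 amol) arranged as a 12 × 12 cyclic Latin
  Square over a constant biological background of several hundred miRNAs,
  with variable library sizes, negative-binomial noise, and optional
  composition / intensity-distortion bias scenarios.
* **Evaluation metrics**: relative log expression (RLE), per-feature
  variance change, the dilution-series bias model, absolute fold-change
  bias, precision–recall curves for differential-expression calls, and
  Spearman fold-change concordance with hierarchical clustering.

The core quantities, in the field's standard notation with x_ij the count of
feature *i* in sample *j* and s_j the library size (column sum):

* scaling factor (total count): d_j = s_baseline / s_j, normalized counts
  x′ = d_j · x;
* MA coordinates between two samples: M_i = log2(x_i1 / x_i2),
  A_i = ½ · log2(x_i1 · x_i2);
* TMM: precision-weighted mean of M over features surviving a 30 % trim in M
  and 5 % trim in A, factors rescaled to geometric mean 1;
* size factor (median-of-ratios): s*_j = median_i(x_ij / g_i) with g_i the
  geometric mean of feature *i* across samples;
* dilution bias model per spike-in: log2(C) = β0 + β1 · log2(a), fitted over
  the samples with amount a > 0; β1 = 1 means counts track the truth;
* precision–recall over |log2 FC| thresholds, with spike-ins whose nominal
  fold change is ≥ 2 (or infinite, the 0 amol comparisons) as positives and
  the constant background as negatives.

## Worked example

```python
import mirnorm as mn

cfg = mn.SimulationConfig(seed=7, composition_fraction=0.05, composition_fold=4.0)
ds = mn.simulate_dataset(cfg)
res = mn.run_benchmark(ds.counts, ds.design, ds.truth,
                       methods=["cpm", "total_count", "upper_quartile", "tmm", "median_ratio"])
print(res.summary.round(3).to_string())
```

prints

```
                fraction_lower  median_beta1  median_r2  mean_pr_auc  pooled_pr_auc  median_abs_bias
method
cpm                      0.452         0.986      0.973        0.798          0.774            0.681
total_count              0.532         0.967      0.975        0.827          0.790            0.660
upper_quartile           0.975         0.955      0.993        0.845          0.841            0.026
tmm                      0.982         0.957      0.992        0.847          0.843            0.032
median_ratio             0.975         0.956      0.993        0.846          0.843            0.005
```

Reading the rows: under a composition-bias scenario (a few dominant miRNAs
4-fold up in half the samples) the column sum is a misleading depth
estimate, so cpm and total-count scaling lower the variance of only ~45–53 %
of background miRNAs and leave a large median fold-change bias (~0.7 log2
units), while the robust estimators (UQ, TMM, median-of-ratios) lower the
variance of ~98 % of background features, keep the dilution slope β1 near 1
with R² ≈ 0.99, dominate the pooled precision–recall area, and leave
essentially no systematic bias.

## Command line

```bash
mirnorm simulate --seed 1 --out sim/              # counts.tsv, truth.tsv, design.tsv
mirnorm filter --counts sim/counts.tsv --out filtered.tsv
mirnorm normalize --counts filtered.tsv --method tmm --out tmm.tsv
mirnorm downsample --counts sim/counts.tsv --depth 100000 --seed 1 --out down.tsv
mirnorm run --seed 1 --out report/                # simulate + full benchmark
mirnorm evaluate --counts sim/counts.tsv --design sim/design.tsv --out report/
```

Every output file starts with a comment header recording the tool version,
command line and seed.

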