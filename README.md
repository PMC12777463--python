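# nichekit

Spatial niche statistics for **rare marker-positive cells**, with the
companion analyses a single-cell / spatial transcriptomics study of a
candidate gene typically needs.

## The problem

High-resolution spatial transcriptomics slides routinely contain tens of
thousands of cells, of which only a handful express a transcript of
interest (e.g. 13 positive cells among ~50,000). Are those rare cells
sitting in *atypical neighborhoods* — say, surrounded by more tumor
epithelium than a random cell would be? With so few positives, parametric
tests are fragile; nichekit implements the natural resampling answer:

1. For each positive cell, find its *k* = 20 nearest neighbors (exact
   2-D Euclidean k-d tree query, self excluded) and record the cell-type
   composition of that neighborhood — a vector on the probability simplex.
2. The observed statistic is the mean composition over the *m* positive
   cells.
3. Build a null by drawing *m* cells uniformly without replacement from
   **all** cells, *B* = 1,000 times, recording each draw's mean neighbor
   composition.
4. For each cell type *t*, the empirical p-value is
   `p_t = #{b : null_mean[b,t] >= observed_t} / B` (ties count as extreme),
   and types with `p_t < 0.05` are called enriched.

The package also provides, behind the same API style:

- **Marker-restricted co-expression** — Pearson/Spearman correlation of two
  genes across cells with detectable marker expression (strictly > 0),
  with an optional zero-target exclusion as a sensitivity analysis; the
  two-sided p comes from `t = r * sqrt((n-2)/(1-r^2))` on *n* − 2 df.
- **Peak-to-gene concordance** — each gene is assigned the nearest
  H3K27ac-style peak within 5 kb of its strand-aware TSS (distance 0
  inside the peak, else bp to the nearest covered base; equidistant ties
  go to the smaller start), then peak logFC is correlated with gene logFC.
- **DEG filtering and overlap significance** — strict `|logFC|` and
  FDR/p cuts, and the hypergeometric upper tail
  `P(X >= k)` (one-sided Fisher) for the overlap of two gene sets in an
  explicit universe, computed in log space so extreme tails survive.
- **qPCR / 3C utilities** — delta-Cq relative expression
  `2^-(Cq_target - Cq_ref)` and BAC-library + reference-locus 3C
  normalization.
- **A synthetic-data generator** — null and enrichment-planted slides,
  zero-inflated correlated expression pairs, and peak/TSS/logFC fixtures,
  all with exported ground truth, so every analysis is testable without
  external data.

The statistical analyses are exposed as scikit-learn-style estimators
(`NeighborhoodEnrichment`, `ExpressionCorrelation`, `NearestPeakAssigner`)
with plain-function wrappers (`run_enrichment`, `correlate`,
`assign_nearest_peak`, ...), plus a `nichekit` command-line interface.

## Worked example

Plant a co-location signal and recover it:

```python
import nichekit as nk

cfg = nk.SlideConfig(
    n_cells=5000,
    type_proportions={"Cancer Epithelial": 0.40, "Stromal": 0.20,
                      "T-cells": 0.15, "Myeloid": 0.10,
                      "B-cells": 0.08, "Endothelial": 0.07},
    m_positive=13, focal_type="Cancer Epithelial",
    enrichment_rho=20.0, seed=1,
)
slide, weights = nk.generate_enriched_slide(cfg)
res = nk.run_enrichment(slide, slide.positive_indices,
                        k=20, B=1000, alpha=0.05, seed=2)
print(res.to_frame().round(4).to_string())
```

```
                   observed_mean  observed_sd  null_mean  p_value  enriched  t_statistic  t_p_value
cell_type
Cancer Epithelial         0.8500       0.1041     0.4074    0.000      True      15.3322     0.0000
Stromal                   0.0500       0.0612     0.1982    1.000     False      -8.7269     0.0000
T-cells                   0.0308       0.0435     0.1422    1.000     False      -9.2397     0.0000
Myeloid                   0.0269       0.0259     0.1014    0.998     False     -10.3526     0.0000
B-cells                   0.0115       0.0219     0.0806    1.000     False     -11.3494     0.0000
Endothelial               0.0308       0.0480     0.0702    0.988     False      -2.9598     0.0119
```

The 13 positive cells see on average 85% cancer-epithelial neighbors
against a null mean of ~41%, so "Cancer Epithelial" is the one enriched
type (permutation `p_value` = 0; the one-sample t-test variant shown
alongside is the labelled alternative, not the primary inference). The
same run from the shell:

```sh
nichekit niche-enrich --cells slide.tsv --marker marker \
    --k 20 --permutations 1000 --alpha 0.05 --seed 2 --out results/run
```

writes `run.enrichment.tsv`, `run.null.tsv`, `run.summary.json` and a
`run.manifest.json` recording all parameters, the seed and input
checksums; the same seed reproduces the result files byte for byte.

Two closed-form one-liners:

```python
>>> nk.overlap_test(310, 383, 47, 20000)   # DEG-overlap upper tail
1.521468240433046e-28
>>> nk.delta_cq(25.0, 22.0)                # three cycles later = 1/8
0.125
```

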