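# Methods

## The neighborhood enrichment test

**Model.** A slide is a set of `n` cells with planar coordinates, a
categorical cell-type label from a declared universe of `T` types, and a
rare positive subpopulation of size `m` (cells whose marker expression is
strictly greater than zero, or an explicit flag). The neighborhood of a
cell is its `k` nearest neighbors under 2-D Euclidean distance, self
excluded; its composition is the vector of type fractions among those
neighbors, a point on the `T`-simplex. The observed statistic is the mean
composition over the `m` positives (per-type sample SD is reported
alongside, ddof = 1, defined as 0 for m = 1).

**Null and inference.** The null resamples `m` distinct cells uniformly
from *all* cells (positives included — the resample universe is the full
dataset) `B` times and records each resample's mean composition. The
per-type empirical p is the fraction of null means greater than or equal
to the observed mean; ties count as extreme, so a type whose observed
value equals every null value gets p = 1, and the test is one-sided in
the enrichment direction. Types with p strictly below alpha (default
0.05) are called enriched. Defaults `k = 20`, `B = 1000` match the study
conditions the synthetic generator emulates.

Assumptions worth stating: the test conditions on the observed geometry
and labels (only the identity of the positive set is resampled), treats
the slide as a single planar section, and makes no assumption about the
spatial point process. Positive cells may appear in other positives'
neighborhoods; no exclusion is applied (configurable nowhere — it is a
property of the definition, documented here).

**Options.** `add_one=True` switches to the (count+1)/(B+1) estimator,
which cannot report exactly 0 — useful when p-values feed downstream
corrections. The default is the plain proportion, matching the counting
definition above. `with_replacement=True` relaxes distinctness within a
resample (off by default: a resample of 13 cells means 13 distinct
cells). `bh_correct=True` additionally computes Benjamini–Hochberg
adjusted p-values across the `T` types and bases calls on them; the
default applies no multiple-testing correction, since the procedure being
emulated thresholds raw p-values. A one-sample t-test of the positives'
per-cell focal-type fractions against the null grand mean is computed
alongside as a clearly labelled alternative (figure-legend style
inference); it is never the primary call. A radius-based neighborhood
(`radius_query`) is provided as a labelled alternative definition; the
fixed-k neighborhood is primary.

**Determinism.** All resampling flows through one seeded NumPy generator;
identical inputs and seed give identical results, and the CLI writes
byte-identical result files for repeated seeded runs.

## Exact kNN with deterministic ties

Queries run through `scipy.spatial.cKDTree`, but the spec of the
neighborhood is stricter than scipy guarantees: equal distances must
resolve by ascending cell index on any platform. The implementation
queries `k + 2` candidates, removes self, orders by (distance, index) via
a stable double argsort, and accepts a row only when the k-th neighbor is
strictly closer than the next candidate; rows with a truncated boundary
tie group (or coincident duplicate coordinates) fall back to an exact
full-distance scan with the same lexicographic order. This keeps the fast
path vectorized while making gridded or degenerate geometries exactly
reproducible.

## Synthetic slides

The generator's defaults are the study-scale conditions: `n = 50,000`
cells, six types dominated by tumor epithelium (40% cancer epithelial,
20% stromal, 15% T-cells, 10% myeloid, 8% B-cells, 7% endothelial — a
plausible mix for an ER+ breast tumor section), `m = 13` positives,
`k = 20`, on a square field of side 1,000 length units (units are
arbitrary; only relative geometry matters).

*Null slides*: coordinates i.i.d. uniform on the square, labels i.i.d.
from the type proportions, positives a uniform random subset.

*Enriched slides*: labels and their marginal distribution are unchanged;
focal-type cells are placed as a mixture of `n_clusters = 5` isotropic
Gaussian clusters (centers uniform, `cluster_sd = 50`, i.e. 5% of the
field side — compact patches) rejection-sampled into the field so density
stays finite at the edges; all other cells remain uniform. Positives are
drawn without replacement with weight `w_i = 1 + rho * f_i`, where `f_i`
is the focal fraction among cell i's `k_local = 20` nearest neighbors.
Injecting enrichment through selection weights rather than relocation
keeps the marginal spatial and type distributions identical between null
and alternative, isolating the neighborhood effect; the returned weights
are the ground truth. At `rho = 0` the draw is uniform; as `rho → ∞`
selection mass becomes proportional to `f_i`, so cells with zero local
focal fraction are never chosen.

What the generator does **not** emulate: platform artifacts (bead
sharing, segmentation error), label-transfer noise, full transcriptomes,
or the unknown spatial point process of a real slide — the Gaussian
cluster model is a stand-in, not a claim about real data. Passing tests
therefore demonstrate calibration and power under this controlled model,
not performance on any particular real tissue.

## Co-expression

Two genes' values are restricted to cells with detectable marker
(strictly > 0; the detectability cut is deliberately strict so a zero
never counts as evidence), optionally also to cells with non-zero target
— the sensitivity analysis for zero inflation. Pearson r is the
product-moment correlation; Spearman uses average ranks (deterministic
under ties). Two-sided p comes from `t = r*sqrt((n-2)/(1-r^2))` on n−2
df, applied to ranks for Spearman. At least 3 cells must survive the
restriction. Because the upstream contract is log-normalized expression,
the module performs no normalization; `log_transform=True` is provided
for raw-scale inputs and applies a natural log *after* the restriction
(it requires strictly positive retained values, so zero-inflated targets
must use the zero-exclusion option first). When the choice of coefficient
is contested, `method="both"` computes and reports both rather than
guessing.

The synthetic pair generator draws standard bivariate normal latents with
correlation `r_true`, maps them through `scale * exp(z)`, and zeroes
entries independently with the dropout probability; the latents are
returned as the oracle. Defaults (`n = 2000`, `r_true = 0.65`, no
dropout, scale 1) are the conditions used by the recovery checks.

## Peak-to-gene assignment and concordance

Coordinates are 0-based half-open (standard BED); a minus-strand gene's
TSS is `end - 1`. Distance from a TSS to a peak is 0 inside the interval,
otherwise base pairs to the nearest covered base — distance-to-feature,
not midpoint distance (midpoint is available as an option). The window is
inclusive at exactly 5,000 bp ("within 5 kb"); equidistant flanking peaks
resolve to the smaller start coordinate, an explicit determinism choice
where the emulated procedure is silent. Assignment scans peaks per
chromosome with a vectorized distance computation; tests compare it
against an independent pure-Python all-pairs scan and against fixture
ground truth. Concordance is then the Pearson (or Spearman) correlation
of (peak logFC, gene logFC) over assigned pairs, p as above, requiring at
least 3 pairs.

The fixture generator spaces gene territories 10 windows apart so
assignments cannot leak between genes, and draws each gene's scenario
from: TSS-containing peak, near peak at a known in-window distance
(sometimes shadowed by a farther in-window decoy, occasionally an exact
equidistant tie exercising the tie rule), a peak strictly beyond the
window, or no peak; leftover peaks land in intergenic deserts. Gene and
truly-assigned-peak logFCs are bivariate normal with correlation
`r_true`; everything else is independent noise.

## DEG filtering and overlap significance

Filtering keeps genes with `|logFC|` strictly above the cut AND the
chosen statistic (FDR or p) strictly below its cut — both boundaries
exclusive, so a gene at exactly the logFC cut is dropped. The overlap
test is the hypergeometric upper tail `P(X >= k)` for drawing `n_b`
elements from a universe containing `n_a` marked ones — the one-sided
Fisher exact test for enrichment. The tail is accumulated from
`hypergeom.logpmf` terms via log-sum-exp, so tails far beyond naive-sum
precision (1e-50 and below) remain accurate. The universe size is a
required explicit argument: silently assuming a genome size would change
the answer by orders of magnitude.

## qPCR and 3C ratios

Delta-Cq assumes perfect doubling per cycle (efficiency fixed at 2;
efficiency-corrected variants are out of scope):
`2^-(Cq_target - Cq_reference)`. The 3C normalization composes two pure
ratios — interaction over BAC-library signal (PCR-efficiency control) and
calibrator over sample reference-locus signal (between-sample
correction); being ratios, the composition order is irrelevant, which is
why the implementation fixes one order without loss of generality. All
inputs must be finite and strictly positive.

## Problem sizes used by the checks

The statistical acceptance checks run at a deliberately chosen desk
scale that preserves the rare-positive regime: calibration uses 300 null
slides of 5,000 cells (5 types, m = 13, k = 20, B = 500, alpha = 0.05),
where per-type rejection rates are expected inside [0.02, 0.08] — a 99%
binomial band around 0.05 widened for the discreteness of B; power uses
100 slides per enrichment strength over rho ∈ {0, 2, 5, 20}; oracle
checks use 50 slides of 1,000 cells for kNN, every feasible configuration
with universe ≤ 12 for the overlap enumeration, 20 fixtures for peak
assignment, and 200 replicates of n = 2,000 for correlation recovery.
Measured under seed 1: mean type-I rate 0.050, power 0.08 / 0.40 / 0.80 /
0.97 across the rho grid, and exact (1.0) agreement on all oracle checks;
`scripts/acceptance.py` recomputes these numbers for any seed.

## Known limitations

- The enrichment test conditions on one slide; it does not model
  between-section variability or spatial autocorrelation of the null
  beyond what resampling from the observed slide captures.
- Empirical p-values are granular at 1/B; with B = 1,000 the smallest
  non-zero p is 0.001 (or 1/1001 with the add-one estimator).
- The 2-D Euclidean metric assumes planar sections; no 3-D support.
- Peak assignment is nearest-within-window only — no weighting by peak
  size, signal, or chromatin contact information.
- The correlation p-values use the t approximation, which is inaccurate
  for very small n (n < ~10) under heavy ties for Spearman.
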