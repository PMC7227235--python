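# Methods

## Problem setting

Unsupervised clustering of scRNA-seq data yields clusters that must be
assigned cell-type identities. `idscore` does this by comparing each
cluster's expression signature with every sample of a labeled reference
panel of sorted-cell profiles and reporting a ranked, z-scored identity
score per (cluster, reference sample) pair. The unit of annotation is the
cluster, not the cell, and the unit of comparison is the reference
*sample*, not the aggregated cell type — several samples of the same type
can (and usually do) co-occupy the top ranks, which is itself useful
evidence.

## Scores

Reference values are assumed log-scale (log-normalized counts or
log-transformed intensities), so the per-sample reference logFC is a
subtraction of the per-gene panel mean, never a ratio of raw values.
Each gene row of the reference logFC matrix is therefore exactly
zero-mean, and the matrix is recomputed whenever the sample set changes.

* **logFC dot product** — the raw sum of products of cluster and
  reference logFC over the cluster's DE genes; not divided by the gene
  count. Normalization would only rescale all of a cluster's scores
  equally, leaving ranks and z-scores unchanged, so the simplest
  convention is used and documented.
* **logFC Spearman / Pearson** — correlations over the same matched DE
  genes. The reference columns are restricted to the cluster's matched
  DE gene set, per cluster.
* **all-genes Spearman / Pearson** — correlations over the full shared
  gene set using the cluster's average expression profile.

Spearman uses average ranks for ties (`scipy.stats.rankdata`) followed by
a Pearson correlation of the ranks, vectorized across the whole panel.
A zero-variance vector on either side of a correlation produces a score
of 0 with a warning instead of NaN, keeping every per-cluster score
vector complete so z-scores remain defined.

Gene matching is case-insensitive (symbols are uppercased at load time),
which makes mouse/human symbol conventions interoperate. Marker genes
absent from the reference are dropped, not zero-filled: zero-filling
would silently reward references with small gene universes. An empty
intersection is a hard error; a matched fraction below 25% of the input
genes triggers a warning (configurable).

## z-scores, ranks, and the confidence heuristic

Within each (cluster, method), z-scores standardize the score vector by
its mean and *population* (divide-by-n) SD. The population convention is
fixed so that the ±1/±2 SD bands shaded in the per-cluster plots are
exactly the |z| = 1 and |z| = 2 contours. Ranks are dense (1 = highest
score) with ties broken by ascending sample id for cross-platform
determinism. Every cluster receives a fully ranked table; no
"unassigned" label is ever emitted, because knowing what a cluster
resembles most is informative even when the resemblance is weak. A top
hit with z > 1 is an informal confidence heuristic surfaced in the
documentation, never enforced.

## Reference preprocessing

* **Variance filtering** keeps exactly `k = ceil(p/100 × G)` genes with
  the largest across-sample variance (population variance; the ranking is
  ddof-invariant), ties broken by ascending symbol. With this rule a
  24197-gene panel keeps 2420 genes at p = 10 and 242 at p = 1. A fixed
  top-k count was chosen over an interpolated quantile cut because it is
  exact, deterministic, and reproduces those worked counts.
* **Cell-type subsetting** retains the samples of user-chosen types
  (labels matched exactly and case-sensitively; case-insensitivity is a
  gene-symbol affordance, not a label one). Pairwise all-genes
  correlations are invariant to subsetting; logFC scores are not, since
  the panel grand mean moves.
* When both are requested, subsetting is applied first and the variance
  filter second, so "highly variable" is judged on the panel actually in
  scope. The opposite order would let discarded cell types decide which
  genes survive.
* Duplicate gene symbols after uppercasing (e.g. probe-level rows) are
  merged by keeping the highest-variance row — the most informative
  measurement — with a warning. Missing or non-numeric expression values
  are hard errors, not imputed: reference panels are curated artifacts
  and silent imputation risks scoring artifacts.

## Synthetic data generator

The generator stands in for real sorted-cell compendia (its default
dimensions, 24197 genes × 296 samples in 20 cell types, mirror a widely
used mouse immune-cell panel). Samples are partitioned round-robin into
cell types; each type's latent mean is a shared baseline profile
(Normal(6, 1.5) per gene) with a private random subset of 150 marker
genes up-shifted by 2.0 log-units (a strong DE effect); samples add
i.i.d. Gaussian noise with SD 0.75 on the log scale. The large
within-type SD is deliberate and realistic: "main" cell types in curated
panels lump heterogeneous fine subsets, so same-type profiles differ
substantially — and it is exactly this per-sample individuality that
makes the *specific* generating sample of a synthetic cluster
identifiable, rather than only its cell type.

Experiments are derived from chosen reference samples: a cluster's
average-expression column is its generating sample plus Gaussian noise
(default SD 0.1 — cluster averages track their source closely), and its
marker table is a one-vs-rest logFC contrast against the other clusters
truncated to the 300 largest-|logFC| genes, mimicking a typical marker
list without a statistical test (the scoring consumes logFCs, not
p-values). An optional fraction of genes can be renamed to exercise
unmatched-gene handling. All draws flow from one integer seed.

What the generator does **not** emulate: UMI counting noise, dropout,
batch effects, cross-platform distribution shifts, or correlated gene
modules. Passing recovery tests therefore demonstrate that the scoring
machinery is correct and discriminative under a Gaussian log-scale
model, not that any particular accuracy will be achieved on real data.

## Test problem sizes

The recovery experiments run on 2000-gene panels with the full 296
samples and 20 cell types (20 seeded replicates, 3 clusters each, all
five methods); the package's accuracy there is 100%. The gene count is
reduced from the
full 24197 because recovery difficulty is governed by the sample/type
structure and the noise ratios, not the gene universe, and 2000 genes
keep the replicated experiment quick. The monotone noise-degradation
property is checked on 500-gene, 60-sample panels over a noise grid
(0.05–16 log-units) averaged over 20 seeds. `scripts/acceptance.py`
builds one full-size panel (24197 × 296) for the filtering and
cardinality measurements.

## Numerical conventions and edge cases

* Correlations are clipped to [−1, 1] to absorb floating-point overshoot.
* Exported CSVs carry 12 significant digits; re-import round-trips to
  ~1e-11 relative tolerance.
* Dot-product scores are linear in the cluster logFC vector; logFC base
  (natural vs log2) is accepted as-is, so scores are comparable within a
  run but not across differently-based inputs.
* Cluster labels are opaque strings ("05" ≠ "5"); marker tables are read
  as text and only the logFC column is coerced numeric.
* `filter_by_variance` never returns fewer than 1 gene by construction
  (ceil rule), but the panel invariant of ≥2 genes and ≥2 samples is
  enforced on every constructed reference, including filter outputs.

## Known limitations

* Per-cluster scoring only; heterogeneous clusters that mix types are
  averaged into one signature.
* No statistical significance is attached to scores; the z-score is a
  relative, panel-dependent quantity and is not comparable across runs
  with different references or filters.
* The reference is held in memory as a dense matrix; panels of ~25k
  genes × several hundred samples are comfortable, single-cell-scale
  references (tens of thousands of columns) are out of scope.
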