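# idscore

Reference-based identity scoring for annotating single-cell RNA-seq
clusters.

After unsupervised clustering of an scRNA-seq experiment, each cluster
still needs a biological label. `idscore` assigns labels objectively by
scoring every cluster's expression signature against every sample of a
labeled reference expression panel — a genes × samples matrix of
log-scale profiles from sorted cells (bulk RNA-seq or microarray), where
each sample carries a known cell-type label. It is aimed at analysts who
have a marker-gene table or per-cluster average expression matrix from a
standard pipeline (e.g. Seurat or scanpy) and a reference panel of their
choice.

## The scoring model

Let $f_{gc}$ be the log fold-change (logFC) of gene $g$ in cluster $c$
from one-vs-rest differential expression, and let $x_{gs}$ be the
log-expression of gene $g$ in reference sample $s$. The reference logFC
is each sample against the panel-wide mean,

$$r_{gs} = x_{gs} - \frac{1}{S}\sum_{s'} x_{gs'},$$

so every gene row of $r$ has zero mean. Five identity scores are
available for a cluster–sample pair, computed over the case-insensitively
matched genes:

1. **logFC dot product** (recommended): $\mathrm{score}(c,s) = \sum_g f_{gc}\, r_{gs}$
   over the cluster's DE genes. Concordant up/down-regulation adds to the
   score; anti-correlated genes subtract from it.
2. **logFC Spearman** and **logFC Pearson**: rank / linear correlation of
   $(f_{gc})_g$ with $(r_{gs})_g$ over the same DE genes.
3. **all-genes Spearman** and **all-genes Pearson**: correlation of the
   cluster's average expression profile with $x_{\cdot s}$ over the full
   shared gene set, ignoring DE status.

Per cluster, scores are converted to z-scores
$z(s) = (\mathrm{score}(s) - \mu)/\sigma$ with $\mu,\sigma$ the mean and
population SD across the panel, and ranked (rank 1 = best). The panel can
first be restricted to its top-$p$% most variable genes and/or to chosen
cell types; all-genes correlations are unaffected by cell-type
subsetting, while the logFC methods change because the panel mean moves.

## Worked example

No reference panel is bundled; the built-in generator creates a seeded
synthetic panel plus an experiment with known ground truth:

```bash
idscore simulate --n-genes 2000 --n-samples 60 --n-cell-types 10 \
    --n-clusters 3 --seed 42 --outdir demo
idscore score --method logfc_dot_product \
    --markers demo/markers.csv \
    --reference demo/reference_expression.csv \
    --metadata demo/reference_metadata.csv \
    --outdir demo/out
```

which logs

```
INFO idscore: reference: 2000 genes x 60 samples, 10 cell types
INFO idscore: logfc_dot_product: 3 clusters x 60 reference samples scored
```

and writes per-cluster score CSVs, top-hit summaries, and plots. The top
of `demo/out/top_hits_logfc_dot_product.csv`:

```
cluster,rank,sample_id,long_label,cell_type,score,z_score
c00,1,S059,CT09_S059,CT09,918.287618684,4.37238390009
c00,2,S029,CT09_S029,CT09,445.457459072,2.1210250281
c00,3,S019,CT09_S019,CT09,409.902574475,1.95173209436
```

Cluster `c00` was generated from reference sample `S059` (cell type
`CT09`, per `demo/truth.json`), and that exact sample ranks first at 4.37
SD above the panel mean — followed by the other `CT09` samples. In
practice a top hit with z-score above ~1 is a reassuring prediction; low
maxima mean the cluster merely *resembles* its best hit. The per-cluster
scatter plots shade the ±1 and ±2 SD bands around the mean score so this
is visible at a glance.

Scoring real data works the same way: point `--markers` at your DE table
(columns `gene`, `cluster`, `avg_logFC`; names configurable) or
`--avg-expression` at a genes × clusters matrix for the all-genes
methods, and supply your reference panel as two CSV/TSV files (expression
with a `gene` column, metadata with `sample_id`, `long_label`,
`cell_type`). Gene symbols are matched case-insensitively, so mouse
(`Cd3e`) and human (`CD3E`) conventions interoperate. See
`idscore score --help`, plus `build-reference` (precompute a filtered
reference logFC matrix) and `plot` (regenerate figures from an exported
scores CSV).

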