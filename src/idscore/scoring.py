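"""Identity scoring of clusters against a labeled reference panel.

Five alternative metrics quantify how much an unknown cluster's expression
signature resembles each reference sample:

``logfc_dot_product``
    Sum over shared DE genes of (cluster logFC) x (reference-sample logFC).
    Factors in both the direction and the magnitude of differential
    expression: concordant up/down regulation adds to the score, strong
    anti-correlation subtracts from it. The recommended default.
``logfc_spearman`` / ``logfc_pearson``
    Rank / linear correlation of the same two logFC vectors over the
    cluster's DE genes.
``all_genes_spearman`` / ``all_genes_pearson``
    Rank / linear correlation of the cluster's average expression against
    each reference sample over the full shared gene set, ignoring DE
    status.

For each cluster the per-sample scores are summarized by z-scores (the
distance of a sample's score from the mean score across the panel, in
population-SD units) and by dense ranks (rank 1 = highest score, ties
broken by ascending sample id). A z-score above ~1 SD is an informal
confidence heuristic, not an enforced threshold: every cluster always
receives a fully ranked table, never an "unassigned" label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .experiment import ClusterExpressionMatrix, ClusterMarkerTable
from .reference import (
    ReferenceExpression,
    ReferenceLogFC,
    compute_reference_logfc,
    filter_by_variance,
    subset_reference,
)

LOGFC_METHODS = ("logfc_dot_product", "logfc_spearman", "logfc_pearson")
ALL_GENES_METHODS = ("all_genes_spearman", "all_genes_pearson")
METHODS = LOGFC_METHODS + ALL_GENES_METHODS

#: fixed column order of an identity-score table
SCORE_COLUMNS = [
    "cluster",
    "sample_id",
    "long_label",
    "cell_type",
    "method",
    "score",
    "z_score",
    "rank",
    "n_genes_used",
]

DEFAULT_MIN_MATCH_FRACTION = 0.25


@dataclass
class GeneMatch:
    """Result of case-insensitive gene-symbol matching between two gene sets."""

    matched_genes: list[str]
    n_input_only: int
    n_reference_only: int

    @property
    def n_matched(self) -> int:
        return len(self.matched_genes)


def match_genes(
    input_genes: list[str],
    reference_genes: list[str],
    min_match_fraction: float = DEFAULT_MIN_MATCH_FRACTION,
) -> GeneMatch:
    """Intersect experimental and reference gene symbols (reference order).

    Both lists are expected uppercased by the loaders, which makes matching
    species-agnostic (mouse ``Cd3e`` meets human ``CD3E``). A warning is
    emitted when fewer than ``min_match_fraction`` of the input genes match;
    an empty intersection is a hard error.
    """
    input_set = set(input_genes)
    matched = [g for g in reference_genes if g in input_set]
    if not matched:
        raise ValueError(
            "no shared genes between input and reference — check species/"
            "symbol conventions"
        )
    n_input_only = len(input_set - set(matched))
    n_reference_only = len(reference_genes) - len(matched)
    fraction = len(matched) / len(input_set)
    if fraction < min_match_fraction:
        warnings.warn(
            f"only {len(matched)}/{len(input_set)} input genes "
            f"({fraction:.1%}) matched the reference",
            stacklevel=2,
        )
    return GeneMatch(
        matched_genes=matched,
        n_input_only=n_input_only,
        n_reference_only=n_reference_only,
    )


def _pearson_against_panel(x: np.ndarray, panel: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``x`` with every column of ``panel``.

    Zero-variance vectors on either side yield a score of 0 (with a
    warning) rather than NaN, keeping the per-sample vector complete so
    z-scores stay defined.
    """
    x = np.asarray(x, dtype=float)
    panel = np.asarray(panel, dtype=float)
    xc = x - x.mean()
    pc = panel - panel.mean(axis=0)
    x_norm = np.sqrt((xc**2).sum())
    p_norm = np.sqrt((pc**2).sum(axis=0))
    denom = x_norm * p_norm
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            "zero-variance vector in correlation; affected scores set to 0",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(degenerate, 0.0, xc @ pc / np.where(degenerate, 1.0, denom))
    return np.clip(r, -1.0, 1.0)


def _spearman_against_panel(x: np.ndarray, panel: np.ndarray) -> np.ndarray:
    """Spearman correlation (average ranks for ties) against each column."""
    xr = rankdata(x)
    pr = rankdata(panel, axis=0)
    return _pearson_against_panel(xr, pr)


def score_logfc_dot_product(
    cluster_logfc: pd.Series, ref_logfc: ReferenceLogFC
) -> pd.Series:
    """Raw dot product of cluster and reference logFC over matched genes.

    The score is the plain sum of products (no per-gene normalization):
    scale affects the magnitude but neither the within-run ranking nor the
    z-scores. Marker genes absent from the reference are dropped, not
    zero-filled.
    """
    match = match_genes(list(cluster_logfc.index), ref_logfc.genes)
    x = cluster_logfc.loc[match.matched_genes].to_numpy(dtype=float)
    panel = ref_logfc.values.loc[match.matched_genes].to_numpy(dtype=float)
    return pd.Series(x @ panel, index=ref_logfc.samples, name="score")


def score_logfc_correlation(
    cluster_logfc: pd.Series, ref_logfc: ReferenceLogFC, flavor: str
) -> pd.Series:
    """Spearman or Pearson correlation of cluster vs reference logFC vectors."""
    if flavor not in ("spearman", "pearson"):
        raise ValueError(f"flavor must be 'spearman' or 'pearson', got {flavor!r}")
    match = match_genes(list(cluster_logfc.index), ref_logfc.genes)
    if match.n_matched < 3:
        raise ValueError(
            f"correlation requires at least 3 matched genes, got {match.n_matched}"
        )
    x = cluster_logfc.loc[match.matched_genes].to_numpy(dtype=float)
    panel = ref_logfc.values.loc[match.matched_genes].to_numpy(dtype=float)
    scorer = (
        _spearman_against_panel if flavor == "spearman" else _pearson_against_panel
    )
    return pd.Series(scorer(x, panel), index=ref_logfc.samples, name="score")


def score_all_genes_correlation(
    cluster_expr: pd.Series, ref: ReferenceExpression, flavor: str
) -> pd.Series:
    """Correlate a cluster's average expression with each reference sample.

    Matching is over the full gene sets, ignoring DE status. Because the
    score of a (cluster, sample) pair depends only on that pair's vectors,
    these scores are invariant to reference subsetting — unlike the
    logFC-based methods, whose reference logFC depends on the panel mean.
    """
    if flavor not in ("spearman", "pearson"):
        raise ValueError(f"flavor must be 'spearman' or 'pearson', got {flavor!r}")
    match = match_genes(list(cluster_expr.index), ref.genes)
    if match.n_matched < 3:
        raise ValueError(
            f"correlation requires at least 3 matched genes, got {match.n_matched}"
        )
    x = cluster_expr.loc[match.matched_genes].to_numpy(dtype=float)
    panel = ref.values.loc[match.matched_genes].to_numpy(dtype=float)
    scorer = (
        _spearman_against_panel if flavor == "spearman" else _pearson_against_panel
    )
    return pd.Series(scorer(x, panel), index=ref.samples, name="score")


def compute_z_scores(scores: pd.Series | np.ndarray) -> np.ndarray:
    """Scores in population-SD units from the across-panel mean.

    Uses the divide-by-n standard deviation; the convention only scales z
    magnitudes and matches the +/-1 and +/-2 SD bands drawn by the plots.
    A constant score vector (SD 0) maps to all-zero z with a warning.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("z-scores need at least 2 samples")
    sd = s.std(ddof=0)
    if sd == 0:
        warnings.warn("constant scores: z-scores set to 0", stacklevel=2)
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def _ranks_high_to_low(scores: np.ndarray, sample_ids: list[str]) -> np.ndarray:
    """Rank 1 = highest score; ties share order by ascending sample id."""
    ids = np.asarray(sample_ids, dtype=object)
    order = np.lexsort((ids, -np.asarray(scores, dtype=float)))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def score_experiment(
    experiment: ClusterMarkerTable | ClusterExpressionMatrix,
    ref: ReferenceExpression,
    method: str,
    keep_top_percent: float | None = None,
    keep_cell_types: list[str] | None = None,
    min_match_fraction: float = DEFAULT_MIN_MATCH_FRACTION,
) -> pd.DataFrame:
    """Score every cluster against every in-scope reference sample.

    The reference is optionally subset to ``keep_cell_types`` and then
    restricted to its ``keep_top_percent`` % most variable genes before any
    scoring; the reference logFC (for logFC methods) is recomputed on the
    in-scope panel. Returns the identity-score table: one row per
    (cluster, sample) with score, per-cluster z-score, rank, and the count
    of matched genes used.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {list(METHODS)}")
    is_logfc = method in LOGFC_METHODS
    if is_logfc and not isinstance(experiment, ClusterMarkerTable):
        raise TypeError(
            f"method {method!r} scores DE-gene logFC signatures and requires "
            "a per-cluster marker table input"
        )
    if not is_logfc and not isinstance(experiment, ClusterExpressionMatrix):
        raise TypeError(
            f"method {method!r} correlates full expression profiles and "
            "requires an average-expression matrix input"
        )

    if keep_cell_types is not None:
        ref = subset_reference(ref, keep_cell_types)
    if keep_top_percent is not None:
        ref = filter_by_variance(ref, keep_top_percent)
    ref_logfc = compute_reference_logfc(ref) if is_logfc else None

    clusters = experiment.clusters
    rows = []
    for cluster in clusters:
        if is_logfc:
            vec = experiment.cluster_logfc(cluster)
            n_used = match_genes(
                list(vec.index), ref.genes, min_match_fraction
            ).n_matched
            if method == "logfc_dot_product":
                scores = score_logfc_dot_product(vec, ref_logfc)
            else:
                scores = score_logfc_correlation(
                    vec, ref_logfc, method.removeprefix("logfc_")
                )
        else:
            vec = experiment.cluster_expression(cluster)
            n_used = match_genes(
                list(vec.index), ref.genes, min_match_fraction
            ).n_matched
            scores = score_all_genes_correlation(
                vec, ref, method.removeprefix("all_genes_")
            )
        z = compute_z_scores(scores)
        ranks = _ranks_high_to_low(scores.to_numpy(), ref.samples)
        rows.append(
            pd.DataFrame(
                {
                    "cluster": cluster,
                    "sample_id": ref.samples,
                    "long_label": ref.metadata["long_label"].to_numpy(),
                    "cell_type": ref.metadata["cell_type"].to_numpy(),
                    "method": method,
                    "score": scores.to_numpy(),
                    "z_score": z,
                    "rank": ranks,
                    "n_genes_used": n_used,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[SCORE_COLUMNS]
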