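"""Reference expression panels.

A reference is a genes x samples matrix of log-scale expression values
(sorted-cell microarray or bulk RNA-seq profiles) together with per-sample
metadata assigning each sample a long label and a coarse cell-type label.
This module loads and validates such panels, derives per-sample log
fold-change (logFC) profiles against the panel-wide mean, restricts the
panel to its most variable genes, and subsets it to chosen cell types.

All values are assumed to be on a log scale already, so the "fold change"
of a sample versus the panel mean is a subtraction, never a ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._io import coerce_numeric_matrix, collapse_duplicate_genes, read_table

REQUIRED_METADATA_COLUMNS = ("sample_id", "long_label", "cell_type")


def _validate_metadata(metadata: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in metadata.columns:
            raise ValueError(
                f"reference metadata is missing required column {col!r} "
                f"(found: {list(metadata.columns)})"
            )
    meta = metadata.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    meta = meta.set_index("sample_id", drop=False)
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValueError(
            f"expression sample(s) missing from metadata: {missing}"
        )
    extra = [s for s in meta.index if s not in set(samples)]
    if extra:
        raise ValueError(f"metadata sample(s) absent from expression: {extra}")
    # align metadata row order to the expression column order
    return meta.loc[samples]


@dataclass
class ReferenceExpression:
    """Validated genes x samples log-expression panel with sample metadata.

    ``values`` is indexed by uppercase gene symbol with one column per
    sample id; ``metadata`` is indexed by sample id (same order as the
    columns) with ``long_label``, ``cell_type`` and optional
    ``description`` columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError(
                "reference needs at least 2 genes and 2 samples, got "
                f"{self.values.shape[0]} x {self.values.shape[1]}"
            )
        if not self.values.index.is_unique:
            raise ValueError("duplicate gene symbols in reference values")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids in reference values")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("reference values contain non-finite entries")
        self.values.columns = self.values.columns.astype(str)
        self.metadata = _validate_metadata(
            self.metadata.reset_index(drop=True)
            if "sample_id" in self.metadata.columns
            else self.metadata.rename_axis("sample_id").reset_index(),
            list(self.values.columns),
        )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def cell_types(self) -> list[str]:
        """Distinct cell-type labels in metadata order."""
        return list(dict.fromkeys(self.metadata["cell_type"]))


@dataclass
class ReferenceLogFC:
    """Per-gene logFC of each reference sample versus the panel-wide mean.

    Every gene row sums to zero across the samples currently in scope; the
    matrix must be recomputed whenever the sample set changes (subsetting
    moves the grand mean).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def load_reference(expr_path: str, metadata_path: str) -> ReferenceExpression:
    """Load a reference panel from an expression CSV/TSV and a metadata CSV/TSV.

    The expression file has a gene-identifier first column and one numeric
    column per sample; the metadata file must key every sample column with
    ``sample_id``, ``long_label`` and ``cell_type`` (optionally
    ``description``). Gene symbols are uppercased; duplicate symbols are
    merged keeping the highest-variance row.
    """
    expr = read_table(expr_path)
    if expr.shape[1] < 3:
        raise ValueError(
            f"{expr_path}: expected a gene column plus at least 2 sample columns"
        )
    expr = expr.set_index(expr.columns[0])
    values = coerce_numeric_matrix(expr, str(expr_path))
    values = collapse_duplicate_genes(values, str(expr_path))
    metadata = read_table(metadata_path)
    return ReferenceExpression(values=values, metadata=metadata)


def compute_reference_logfc(ref: ReferenceExpression) -> ReferenceLogFC:
    """LogFC of every sample against the across-sample mean, per gene.

    Because values are log-scale, the fold change is a subtraction:
    ``out[g, s] = values[g, s] - mean_s(values[g, .])``. Each output row
    therefore has exactly zero mean.
    """
    centered = ref.values.sub(ref.values.mean(axis=1), axis=0)
    return ReferenceLogFC(values=centered, metadata=ref.metadata)


def filter_by_variance(
    ref: ReferenceExpression, keep_top_percent: float
) -> ReferenceExpression:
    """Restrict the panel to its top ``keep_top_percent`` % most variable genes.

    Keeps exactly ``k = ceil(keep_top_percent / 100 * n_genes)`` genes with
    the largest across-sample variance; variance ties are broken by
    ascending gene symbol. Sample set and metadata are unchanged; the gene
    order of the original panel is preserved in the output.
    """
    if not 0 < keep_top_percent <= 100:
        raise ValueError(
            f"keep_top_percent must be in (0, 100], got {keep_top_percent}"
        )
    n = ref.n_genes
    k = math.ceil(keep_top_percent / 100.0 * n)
    variances = ref.values.var(axis=1, ddof=0)
    ranked = sorted(ref.genes, key=lambda g: (-variances[g], g))
    keep = set(ranked[:k])
    kept_in_order = [g for g in ref.genes if g in keep]
    return ReferenceExpression(
        values=ref.values.loc[kept_in_order], metadata=ref.metadata.copy()
    )


def subset_reference(
    ref: ReferenceExpression, keep_cell_types: set[str] | list[str]
) -> ReferenceExpression:
    """Retain only samples whose cell type is in ``keep_cell_types``.

    Labels are matched exactly (case-sensitive). Any downstream logFC must
    be recomputed on the result: dropping samples changes the per-gene
    grand mean, so logFC-based scores are not invariant to subsetting.
    """
    keep = set(keep_cell_types)
    valid = set(ref.metadata["cell_type"])
    unknown = sorted(keep - valid)
    if unknown:
        raise ValueError(
            f"unknown cell type label(s) {unknown}; valid labels: {sorted(valid)}"
        )
    mask = ref.metadata["cell_type"].isin(keep)
    samples = list(ref.metadata.index[mask])
    if len(samples) < 2:
        raise ValueError(
            f"subsetting to {sorted(keep)} leaves {len(samples)} sample(s); "
            "at least 2 are required"
        )
    return ReferenceExpression(
        values=ref.values[samples], metadata=ref.metadata.loc[samples].copy()
    )
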