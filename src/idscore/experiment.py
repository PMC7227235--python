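"""Experimental inputs: per-cluster marker tables and average-expression matrices.

Two input shapes are accepted, matching what standard scRNA-seq pipelines
emit after clustering:

* a long-format table of differentially expressed genes per cluster with
  their log fold-changes (one-vs-rest marker finding output), consumed by
  the logFC-based scoring methods; and
* a genes x clusters matrix of average log-normalized expression,
  consumed by the all-genes correlation methods.

The logFC base (natural log vs log2) is taken as given; dot products are
scale-covariant and correlations scale-invariant, so scores are comparable
within one run regardless of base. Cluster labels are opaque strings and
never reformatted (so "05" and "5" stay distinct).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._io import (
    coerce_numeric_matrix,
    collapse_duplicate_genes,
    infer_delimiter,
    read_table,
)

DEFAULT_GENE_COL = "gene"
DEFAULT_CLUSTER_COL = "cluster"
DEFAULT_LOGFC_COL = "avg_logFC"


@dataclass
class ClusterMarkerTable:
    """Long-format (gene, cluster, logfc) records of per-cluster DE genes."""

    table: pd.DataFrame  # columns: gene (uppercase), cluster (str), logfc (float)

    def __post_init__(self) -> None:
        expected = ["gene", "cluster", "logfc"]
        if list(self.table.columns) != expected:
            raise ValueError(
                f"marker table must have columns {expected}, "
                f"got {list(self.table.columns)}"
            )
        if len(self.table) == 0:
            raise ValueError("marker table has no rows")
        if not np.isfinite(self.table["logfc"].to_numpy()).all():
            raise ValueError("marker table contains non-finite logFC values")
        if self.table.duplicated(["gene", "cluster"]).any():
            raise ValueError("duplicate (gene, cluster) pairs in marker table")

    @property
    def clusters(self) -> list[str]:
        """Distinct cluster labels in order of first appearance."""
        return list(dict.fromkeys(self.table["cluster"]))

    def cluster_logfc(self, cluster: str) -> pd.Series:
        """The marker logFC vector of one cluster, indexed by gene symbol."""
        sub = self.table[self.table["cluster"] == cluster]
        if len(sub) == 0:
            raise KeyError(f"unknown cluster {cluster!r}")
        return pd.Series(
            sub["logfc"].to_numpy(), index=sub["gene"].to_numpy(), name=cluster
        )


@dataclass
class ClusterExpressionMatrix:
    """Genes x clusters matrix of average log-expression (all genes)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("average-expression matrix is empty")
        if not self.values.index.is_unique:
            raise ValueError("duplicate gene symbols in average-expression matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("average-expression matrix has non-finite entries")
        self.values.columns = self.values.columns.astype(str)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.values.columns)

    def cluster_expression(self, cluster: str) -> pd.Series:
        return self.values[cluster]


def load_marker_table(
    path: str,
    gene_col: str = DEFAULT_GENE_COL,
    cluster_col: str = DEFAULT_CLUSTER_COL,
    logfc_col: str = DEFAULT_LOGFC_COL,
) -> ClusterMarkerTable:
    """Load a per-cluster marker table from CSV/TSV.

    Column names are configurable to cover the common marker-finding
    dialects (e.g. ``avg_logFC``, ``avg_log2FC``). Gene symbols are
    uppercased; duplicated (gene, cluster) rows are resolved by keeping the
    record with the largest ``|logfc|``, with a warning.
    """
    # read everything as text so cluster labels like "05" survive verbatim
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    raw = pd.read_csv(path, sep=infer_delimiter(path), dtype=str)
    for col in (gene_col, cluster_col, logfc_col):
        if col not in raw.columns:
            raise ValueError(
                f"{path}: column {col!r} not found; available columns: "
                f"{list(raw.columns)}"
            )
    if len(raw) == 0:
        raise ValueError(f"{path}: marker table has no rows")
    table = pd.DataFrame(
        {
            "gene": raw[gene_col].astype(str).str.upper(),
            "cluster": raw[cluster_col].astype(str),
            "logfc": pd.to_numeric(raw[logfc_col], errors="coerce"),
        }
    )
    if table["logfc"].isna().any():
        row = int(table["logfc"].isna().to_numpy().nonzero()[0][0])
        raise ValueError(
            f"{path}: non-numeric logFC value {raw[logfc_col].iloc[row]!r} "
            f"in row {row}"
        )
    dup = table.duplicated(["gene", "cluster"], keep=False)
    if dup.any():
        n_before = len(table)
        table = (
            table.assign(_abs=table["logfc"].abs())
            .sort_values("_abs", ascending=False, kind="stable")
            .drop_duplicates(["gene", "cluster"], keep="first")
            .drop(columns="_abs")
            .sort_index()
        )
        warnings.warn(
            f"{path}: resolved {n_before - len(table)} duplicate "
            "(gene, cluster) row(s) by keeping the largest |logFC|",
            stacklevel=2,
        )
    return ClusterMarkerTable(table=table.reset_index(drop=True))


def load_avg_expression(path: str) -> ClusterExpressionMatrix:
    """Load a genes x clusters average-expression matrix from CSV/TSV.

    First column holds gene identifiers; remaining columns are numeric,
    one per cluster. Symbols are uppercased and duplicates merged as in
    reference loading (highest-variance row kept).
    """
    raw = read_table(path)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected a gene column plus >=1 cluster column")
    raw = raw.set_index(raw.columns[0])
    values = coerce_numeric_matrix(raw, str(path))
    values = collapse_duplicate_genes(values, str(path))
    return ClusterExpressionMatrix(values=values)
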