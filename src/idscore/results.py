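"""Summaries and CSV export of identity-score tables."""

from __future__ import annotations

import pandas as pd

from .scoring import SCORE_COLUMNS

#: column order of a top-hits summary table
TOP_HITS_COLUMNS = [
    "cluster",
    "rank",
    "sample_id",
    "long_label",
    "cell_type",
    "score",
    "z_score",
]

DEFAULT_SUMMARY_N = 5


def top_hits(table: pd.DataFrame, n: int = DEFAULT_SUMMARY_N) -> pd.DataFrame:
    """The ``n`` highest-scoring reference samples per cluster, rank-ordered.

    Operates on a single-method identity-score table; summarizes samples
    (not aggregated cell types), so several samples of the same type may
    appear. If ``n`` exceeds the panel size all samples are returned.
    """
    if n < 1:
        raise ValueError(f"summary depth must be >= 1, got {n}")
    methods = table["method"].unique()
    if len(methods) != 1:
        raise ValueError(
            f"top_hits expects a single-method table, found methods {list(methods)}"
        )
    out = (
        table[table["rank"] <= n]
        .sort_values(["cluster", "rank"], kind="stable")
        .reset_index(drop=True)
    )
    return out[TOP_HITS_COLUMNS]


def export_scores(table: pd.DataFrame, path: str) -> str:
    """Write an identity-score or top-hits table to CSV.

    Fixed column order, minimal quoting, UTF-8, header always present;
    floats at 12 significant digits so a re-import is lossless for
    practical purposes.
    """
    if len(table) == 0:
        raise ValueError("refusing to export an empty table")
    if list(table.columns) not in (SCORE_COLUMNS, TOP_HITS_COLUMNS):
        raise ValueError(
            f"unrecognized table schema: {list(table.columns)}"
        )
    table.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")
    return str(path)


def load_scores(path: str) -> pd.DataFrame:
    """Re-import a CSV written by :func:`export_scores`."""
    df = pd.read_csv(path, dtype={"cluster": str, "sample_id": str})
    if list(df.columns) not in (SCORE_COLUMNS, TOP_HITS_COLUMNS):
        raise ValueError(f"{path}: not an identity-score or top-hits CSV")
    return df
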