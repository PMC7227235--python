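"""Shared helpers for reading delimited expression tables."""

from __future__ import annotations

import os
import warnings

import pandas as pd

_TAB_EXTENSIONS = {".tsv", ".tab", ".txt"}


def infer_delimiter(path: str) -> str:
    """Choose comma or tab based on the file extension (.tsv/.tab/.txt -> tab)."""
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in _TAB_EXTENSIONS else ","


def read_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    return pd.read_csv(path, sep=infer_delimiter(path))


def coerce_numeric_matrix(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Validate that every cell of ``df`` is numeric and finite.

    Raises ValueError naming the first offending row label and column.
    """
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            value = df.loc[row, col]
            raise ValueError(
                f"{what}: non-numeric or missing value {value!r} "
                f"at gene {row!r}, column {col!r}"
            )
        out[col] = coerced.astype(float)
    result = pd.DataFrame(out, index=df.index)
    import numpy as np

    if not np.isfinite(result.to_numpy()).all():
        rows, cols = (~np.isfinite(result.to_numpy())).nonzero()
        raise ValueError(
            f"{what}: non-finite value at gene {result.index[rows[0]]!r}, "
            f"column {result.columns[cols[0]]!r}"
        )
    return result


def collapse_duplicate_genes(values: pd.DataFrame, what: str) -> pd.DataFrame:
    """Uppercase the gene index and merge duplicate symbols.

    When several rows share a symbol after uppercasing, the row with the
    highest variance across columns is kept (the most informative
    measurement); a warning reports how many rows were merged away.
    """
    values = values.copy()
    values.index = values.index.astype(str).str.upper()
    if values.index.is_unique:
        return values
    n_before = len(values)
    variances = values.var(axis=1, ddof=0)
    order = (
        pd.DataFrame({"var": variances})
        .assign(pos=range(n_before))
        .sort_values(["var", "pos"], ascending=[False, True])
    )
    keep_pos = {}
    for pos, gene in zip(order["pos"], order.index):
        if gene not in keep_pos:
            keep_pos[gene] = pos
    kept = values.iloc[sorted(keep_pos.values())]
    warnings.warn(
        f"{what}: merged {n_before - len(kept)} duplicate gene row(s) after "
        "uppercasing; kept the highest-variance row per symbol",
        stacklevel=2,
    )
    return kept
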