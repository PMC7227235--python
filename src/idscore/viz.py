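"""Plots: per-cluster score scatter with SD bands, and a top-hits summary.

Both plots color points by reference cell type with a deterministic
palette (colors assigned by sorted cell-type name) and are written as
static SVG or PNG files, chosen by the output extension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib.figure import Figure
from matplotlib.lines import Line2D

from .results import TOP_HITS_COLUMNS


def _palette(cell_types: list[str]) -> dict[str, tuple]:
    """Deterministic cell-type -> color map (sorted names over tab20)."""
    import matplotlib

    cmap = matplotlib.colormaps["tab20"]
    ordered = sorted(set(cell_types))
    return {ct: cmap(i % 20) for i, ct in enumerate(ordered)}


def plot_cluster_scores(
    table: pd.DataFrame, cluster: str, out_path: str
) -> Figure:
    """Scatter of one cluster's identity scores across the reference panel.

    X positions follow the reference metadata order; shaded horizontal
    bands span the mean +/- 1 and +/- 2 population SD of this cluster's
    scores, so a point clearing the outer band edge has |z| > 2 under the
    same SD convention used for z-scores.
    """
    methods = table["method"].unique()
    if len(methods) != 1:
        raise ValueError(f"expected a single-method table, got {list(methods)}")
    sub = table[table["cluster"] == cluster]
    if len(sub) == 0:
        raise ValueError(
            f"unknown cluster {cluster!r}; clusters present: "
            f"{list(table['cluster'].unique())}"
        )
    scores = sub["score"].to_numpy(dtype=float)
    mean, sd = scores.mean(), scores.std(ddof=0)

    fig = Figure(figsize=(11, 4.5))
    ax = fig.add_subplot(111)
    ax.axhspan(mean - 2 * sd, mean + 2 * sd, color="0.92", zorder=0)
    ax.axhspan(mean - sd, mean + sd, color="0.84", zorder=0)
    ax.axhline(mean, color="0.5", lw=0.8, zorder=1)

    colors = _palette(list(sub["cell_type"]))
    x = np.arange(len(sub))
    for cell_type in sorted(colors):
        mask = (sub["cell_type"] == cell_type).to_numpy()
        ax.scatter(
            x[mask],
            scores[mask],
            s=18,
            color=colors[cell_type],
            label=cell_type,
            zorder=2,
        )
    ax.set_xlabel("reference sample (metadata order)")
    ax.set_ylabel(f"identity score ({methods[0]})")
    ax.set_title(f"cluster {cluster}: scores across {len(sub)} reference samples")
    ax.legend(
        fontsize=7, ncol=2, frameon=False, loc="center left", bbox_to_anchor=(1, 0.5)
    )
    fig.tight_layout()
    fig.savefig(out_path)
    return fig


def plot_top_summary(top: pd.DataFrame, out_path: str) -> Figure:
    """One panel per cluster showing its top-N reference samples."""
    if len(top) == 0:
        raise ValueError("empty top-hits table")
    if list(top.columns) != TOP_HITS_COLUMNS:
        raise ValueError(f"expected a top-hits table, got columns {list(top.columns)}")
    clusters = list(dict.fromkeys(top["cluster"]))
    colors = _palette(list(top["cell_type"]))

    fig = Figure(figsize=(3.2 * len(clusters) + 1.5, 4))
    axes = fig.subplots(1, len(clusters), squeeze=False, sharey=False)[0]
    for ax, cluster in zip(axes, clusters):
        sub = top[top["cluster"] == cluster]
        for _, row in sub.iterrows():
            ax.scatter(
                row["rank"],
                row["score"],
                s=40,
                color=colors[row["cell_type"]],
                zorder=2,
            )
        ax.set_title(f"cluster {cluster}", fontsize=9)
        ax.set_xlabel("rank")
        ax.set_xticks(sorted(sub["rank"].unique()))
    axes[0].set_ylabel("identity score")
    handles = [
        Line2D([], [], marker="o", ls="", color=colors[ct], label=ct)
        for ct in sorted(colors)
    ]
    fig.legend(handles=handles, fontsize=7, loc="center right", frameon=False)
    fig.tight_layout(rect=(0, 0, 0.86, 1))
    fig.savefig(out_path)
    return fig
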