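"""Seeded synthetic references and experiments with known ground truth.

The generator emulates the structure of sorted-cell reference panels
(e.g. the murine immune-cell compendium of 296 microarray samples over
24197 genes and 20 main cell types): samples are partitioned into labeled
cell types, each type carries a latent mean log-expression profile
(a shared baseline plus type-specific up-shifts on a random marker gene
subset), and individual samples scatter around their type mean with
Gaussian noise on the log scale.

Experimental inputs are then derived from chosen reference samples: a
cluster's average-expression profile is its generating sample plus
Gaussian noise, and its marker table is a one-vs-rest logFC contrast
against the other clusters, truncated to the largest-|logFC| genes —
mimicking standard marker finding without a statistical test. The
cluster -> generating-sample map is the recoverable ground truth.

Defaults (all on the log-expression scale): marker up-shift 2.0 log-units
(a strong DE effect), within-type sample noise SD 0.75 (main cell types
in sorted-cell panels lump heterogeneous fine subsets, so profiles of the
same main type differ substantially — and it is exactly this per-sample
individuality that makes the generating sample identifiable), cluster
noise SD 0.1 (cluster averages track their source closely), 300 marker
genes per cluster (the order of a typical one-vs-rest DE gene list).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .experiment import ClusterExpressionMatrix, ClusterMarkerTable
from .reference import ReferenceExpression

DEFAULT_N_GENES = 24197
DEFAULT_N_SAMPLES = 296
DEFAULT_N_CELL_TYPES = 20
DEFAULT_MARKER_SHIFT = 2.0
DEFAULT_SAMPLE_NOISE_SD = 0.75
DEFAULT_TYPE_MARKERS = 150
DEFAULT_CLUSTER_NOISE_SD = 0.1
DEFAULT_N_MARKER_GENES = 300


@dataclass
class SyntheticTruth:
    """Ground truth of a generated experiment.

    Maps each cluster label to the reference sample it was generated from,
    and records the generator settings needed to reproduce it.
    """

    cluster_sources: dict[str, str]
    noise_sd: float = DEFAULT_CLUSTER_NOISE_SD
    n_marker_genes: int = DEFAULT_N_MARKER_GENES
    seed: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def generate_reference(
    n_genes: int = DEFAULT_N_GENES,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_cell_types: int = DEFAULT_N_CELL_TYPES,
    seed: int = 0,
    marker_shift: float = DEFAULT_MARKER_SHIFT,
    sample_noise_sd: float = DEFAULT_SAMPLE_NOISE_SD,
    n_type_markers: int = DEFAULT_TYPE_MARKERS,
) -> ReferenceExpression:
    """Generate a labeled synthetic reference panel.

    Samples are split as evenly as possible over ``n_cell_types`` types;
    each type up-shifts a private random subset of ``n_type_markers`` genes
    by ``marker_shift`` log-units above a shared baseline profile, and each
    sample adds i.i.d. Gaussian noise (``sample_noise_sd``). Fully
    reproducible from ``seed``.
    """
    if n_cell_types < 2 or n_samples < n_cell_types or n_genes < 2:
        raise ValueError(
            "need n_genes >= 2 and n_samples >= n_cell_types >= 2, got "
            f"n_genes={n_genes}, n_samples={n_samples}, n_cell_types={n_cell_types}"
        )
    if n_type_markers > n_genes:
        raise ValueError("n_type_markers cannot exceed n_genes")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    # round-robin partition keeps type sizes within 1 of each other
    type_of_sample = [i % n_cell_types for i in range(n_samples)]
    cell_types = [f"CT{i:02d}" for i in range(n_cell_types)]

    baseline = rng.normal(loc=6.0, scale=1.5, size=n_genes)
    type_means = np.tile(baseline, (n_cell_types, 1))
    for t in range(n_cell_types):
        markers = rng.choice(n_genes, size=n_type_markers, replace=False)
        type_means[t, markers] += marker_shift

    values = np.empty((n_genes, n_samples))
    for j, t in enumerate(type_of_sample):
        values[:, j] = type_means[t] + rng.normal(0.0, sample_noise_sd, n_genes)

    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "long_label": [
                f"{cell_types[t]}_{s}" for s, t in zip(samples, type_of_sample)
            ],
            "cell_type": [cell_types[t] for t in type_of_sample],
            "description": "synthetic sorted-cell profile",
        }
    )
    return ReferenceExpression(
        values=pd.DataFrame(values, index=genes, columns=samples),
        metadata=metadata,
    )


def make_truth(
    ref: ReferenceExpression,
    n_clusters: int = 5,
    noise_sd: float = DEFAULT_CLUSTER_NOISE_SD,
    n_marker_genes: int = DEFAULT_N_MARKER_GENES,
    seed: int = 0,
) -> SyntheticTruth:
    """Pick generating samples from distinct cell types for each cluster."""
    if not 2 <= n_clusters:
        raise ValueError("need at least 2 clusters for one-vs-rest marker logFC")
    cell_types = ref.cell_types
    if n_clusters > len(cell_types):
        raise ValueError(
            f"n_clusters={n_clusters} exceeds the {len(cell_types)} cell types"
        )
    rng = np.random.default_rng(seed)
    chosen_types = rng.choice(len(cell_types), size=n_clusters, replace=False)
    sources = {}
    for k, t in enumerate(chosen_types):
        candidates = ref.metadata.index[
            ref.metadata["cell_type"] == cell_types[t]
        ].to_list()
        sources[f"c{k:02d}"] = candidates[int(rng.integers(len(candidates)))]
    return SyntheticTruth(
        cluster_sources=sources,
        noise_sd=noise_sd,
        n_marker_genes=n_marker_genes,
        seed=seed,
    )


def generate_experiment(
    ref: ReferenceExpression,
    truth: SyntheticTruth,
    rename_fraction: float = 0.0,
) -> tuple[ClusterMarkerTable, ClusterExpressionMatrix]:
    """Derive a marker table and average-expression matrix from the truth.

    Each cluster's expression column is its generating sample plus
    Gaussian noise of ``truth.noise_sd`` (0 gives the noiseless limit).
    Marker logFC is each cluster versus the mean of the other clusters;
    the ``n_marker_genes`` largest-|logFC| genes are kept per cluster.
    ``rename_fraction`` renames that fraction of genes in the experimental
    outputs (prefix ``XG``) to exercise unmatched-gene handling.
    """
    if truth.noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {truth.noise_sd}")
    if not 0 <= rename_fraction <= 1:
        raise ValueError("rename_fraction must be in [0, 1]")
    missing = [s for s in truth.cluster_sources.values() if s not in ref.samples]
    if missing:
        raise ValueError(f"truth references unknown sample(s): {missing}")
    clusters = list(truth.cluster_sources)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for one-vs-rest marker logFC")

    rng = np.random.default_rng(truth.seed)
    expr = np.column_stack(
        [
            ref.values[truth.cluster_sources[c]].to_numpy()
            + (
                rng.normal(0.0, truth.noise_sd, ref.n_genes)
                if truth.noise_sd > 0
                else 0.0
            )
            for c in clusters
        ]
    )
    genes = np.asarray(ref.genes, dtype=object)
    if rename_fraction > 0:
        n_rename = int(round(rename_fraction * len(genes)))
        idx = rng.choice(len(genes), size=n_rename, replace=False)
        genes = genes.copy()
        genes[idx] = [f"XG{genes[i]}" for i in idx]

    avg = ClusterExpressionMatrix(
        values=pd.DataFrame(expr, index=list(genes), columns=clusters)
    )

    records = []
    for j, cluster in enumerate(clusters):
        rest = expr[:, [i for i in range(len(clusters)) if i != j]].mean(axis=1)
        logfc = expr[:, j] - rest
        top = np.argsort(-np.abs(logfc), kind="stable")[: truth.n_marker_genes]
        top = sorted(top)  # keep marker rows in gene order
        records.append(
            pd.DataFrame(
                {"gene": genes[top], "cluster": cluster, "logfc": logfc[top]}
            )
        )
    markers = ClusterMarkerTable(table=pd.concat(records, ignore_index=True))
    return markers, avg
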