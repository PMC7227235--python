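import numpy as np
import pandas as pd
import pytest

from idscore import ReferenceExpression


def make_reference(values: np.ndarray, genes, samples, cell_types=None):
    """Build a validated ReferenceExpression from raw pieces."""
    cell_types = cell_types or ["T" for _ in samples]
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "long_label": [f"{ct}_{s}" for s, ct in zip(samples, cell_types)],
            "cell_type": cell_types,
        }
    )
    return ReferenceExpression(
        values=pd.DataFrame(values, index=genes, columns=samples),
        metadata=metadata,
    )


@pytest.fixture
def toy_reference():
    """4 genes x 4 samples, two cell types with different group means."""
    values = np.array(
        [
            [1.0, 2.0, 5.0, 6.0],
            [4.0, 4.5, 1.0, 0.5],
            [2.0, 2.0, 2.0, 2.0],
            [0.0, 1.0, 2.0, 3.0],
        ]
    )
    return make_reference(
        values,
        genes=["GA", "GB", "GC", "GD"],
        samples=["s1", "s2", "s3", "s4"],
        cell_types=["X", "X", "Y", "Y"],
    )


@pytest.fixture
def random_reference():
    """Seeded 50-gene x 10-sample panel over 3 cell types."""
    rng = np.random.default_rng(42)
    values = rng.normal(5, 2, size=(50, 10))
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"s{i:02d}" for i in range(10)]
    cell_types = [f"T{i % 3}" for i in range(10)]
    return make_reference(values, genes, samples, cell_types)


def write_reference_csv(ref: ReferenceExpression, tmp_path, stem="ref"):
    expr = tmp_path / f"{stem}_expression.csv"
    meta = tmp_path / f"{stem}_metadata.csv"
    ref.values.rename_axis("gene").to_csv(expr)
    ref.metadata.to_csv(meta, index=False)
    return str(expr), str(meta)
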