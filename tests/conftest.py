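import numpy as np
import pytest

from spotpie import ExpressionMatrix, normalize_log


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Six spots in two well-separated expression blobs over three genes."""
    rng = np.random.default_rng(7)
    blob_a = rng.normal([1, 1, 1], 0.05, size=(3, 3))
    blob_b = rng.normal([20, 20, 20], 0.05, size=(3, 3))
    values = np.abs(np.vstack([blob_a, blob_b]))
    return ExpressionMatrix(
        values=values,
        spot_ids=tuple(f"{i + 1}x1" for i in range(6)),
        gene_names=("g1", "g2", "g3"),
        normalized=True,
    )


@pytest.fixture
def counts_matrix() -> ExpressionMatrix:
    """Small raw-count matrix for normalization tests."""
    values = np.array([[10.0, 90.0, 0.0], [50.0, 50.0, 0.0], [5.0, 0.0, 5.0]])
    return ExpressionMatrix(
        values=values,
        spot_ids=("1x1", "1x2", "2x1"),
        gene_names=("gA", "gB", "gC"),
    )


@pytest.fixture
def normalized_counts(counts_matrix) -> ExpressionMatrix:
    return normalize_log(counts_matrix, scale=100.0)
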