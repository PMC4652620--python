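import numpy as np
import pandas as pd
import pytest

from mirnorm.count_core import CountMatrix


@pytest.fixture
def tiny_matrix():
    """3 features x 2 samples with column sums [9, 12]."""
    df = pd.DataFrame(
        [[1, 2], [3, 4], [5, 6]],
        index=["hsa-miR-a", "hsa-miR-b", "hsa-miR-c"],
        columns=["S1", "S2"],
    )
    return CountMatrix(df)


@pytest.fixture
def identical_columns():
    """4 features x 3 identical samples (fixed point of every method).

    Columns sum to 1e6 so the fixed-point property holds for cpm too, whose
    output scale is pinned to counts-per-million.
    """
    col = [50_000.0, 150_000.0, 300_000.0, 500_000.0]
    df = pd.DataFrame(
        {s: col for s in ["S1", "S2", "S3"]},
        index=[f"hsa-miR-{i}" for i in range(4)],
    )
    return CountMatrix(df)


def random_counts(n_features=30, n_samples=4, seed=0, scale=200.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.poisson(rng.gamma(2.0, scale / 2.0, size=(n_features, n_samples))),
        index=[f"f{i:03d}" for i in range(n_features)],
        columns=[f"S{j + 1}" for j in range(n_samples)],
    )
    return CountMatrix(df)
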