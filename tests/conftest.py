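import numpy as np
import pandas as pd
import pytest

from phosphowrangle.matrix import PhosphoMatrix

NA = np.nan


@pytest.fixture
def toy_matrix():
    """g1 observed in s1,s2,s3 (5,3,2); g2 only in s1 (4)."""
    df = pd.DataFrame(
        {"s1": [5.0, 4.0], "s2": [3.0, NA], "s3": [2.0, NA]},
        index=["g1", "g2"],
    )
    return PhosphoMatrix(df)


@pytest.fixture
def dense_matrix():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.integers(1, 20, size=(6, 5)).astype(float),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(5)],
    )
    return PhosphoMatrix(df)


def random_sparse_matrix(n_genes, n_samples, missing_frac, seed):
    """Random nonnegative matrix with ~missing_frac NaNs, valid invariants."""
    rng = np.random.default_rng(seed)
    values = rng.integers(1, 50, size=(n_genes, n_samples)).astype(float)
    mask = rng.random((n_genes, n_samples)) < missing_frac
    values[mask] = np.nan
    # guarantee every row/column keeps one observation
    for i in range(n_genes):
        if np.isnan(values[i]).all():
            values[i, rng.integers(n_samples)] = float(rng.integers(1, 50))
    for j in range(n_samples):
        if np.isnan(values[:, j]).all():
            values[rng.integers(n_genes), j] = float(rng.integers(1, 50))
    df = pd.DataFrame(
        values,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    return PhosphoMatrix(df)
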