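import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def four_lib_matrix():
    """Small 4-library matrix with one obvious trap-preferential gene."""
    return pd.DataFrame(
        {
            "FlwL": [10, 40, 12, 5, 0],
            "ShtL": [10, 0, 10, 5, 0],
            "TrpL": [10, 0, 10, 5, 0],
            "StsL": [10, 0, 10, 5, 0],
        },
        index=[f"g{i}" for i in range(5)],
        dtype=float,
    )


def random_count_matrix(rng, n_genes=50, n_libs=4):
    """Tie-free positive matrix for normalization/entropy property tests."""
    values = rng.lognormal(0.0, 1.0, size=(n_genes, n_libs))
    return pd.DataFrame(
        values,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"L{j}" for j in range(n_libs)],
    )
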