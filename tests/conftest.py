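import numpy as np
import pandas as pd
import pytest

from enrichseq.io import CountMatrix
from enrichseq.synthetic import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated experiment shared across read-only tests."""
    params = SimParams(n_taxa=40, depth=5_000, seq_length=400, rng_seed=7)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def study_dataset():
    """Study-condition simulation (200 taxa, depth 10^4), without sequences."""
    params = SimParams(n_taxa=200, depth=10_000, rng_seed=7)
    return simulate_dataset(params, with_sequences=False)


@pytest.fixture()
def toy_counts():
    """Tiny hand-written count matrix with metadata."""
    counts = pd.DataFrame(
        {
            "s1_d0_DNA": [10, 5, 0, 1],
            "s1_d12_DNA": [2, 8, 4, 2],
            "s1_d0_RNA": [4, 9, 1, 2],
            "s1_d12_RNA": [1, 12, 2, 1],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    meta = pd.DataFrame(
        {
            "source": ["s1"] * 4,
            "day": [0, 12, 0, 12],
            "molecule": ["DNA", "DNA", "RNA", "RNA"],
        },
        index=counts.columns,
    )
    return CountMatrix(counts, meta)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
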