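import numpy as np
import pandas as pd
import pytest

import countql as cq


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """Deterministic 8-gene, 4-sample dataset with two groups."""
    counts = np.array(
        [
            [10, 12, 30, 28],
            [100, 90, 110, 95],
            [0, 0, 0, 0],
            [5, 7, 6, 4],
            [50, 55, 20, 18],
            [1, 0, 2, 1],
            [200, 210, 190, 205],
            [8, 9, 40, 35],
        ],
        dtype=float,
    )
    return cq.make_dataset(counts, group=["A", "A", "B", "B"])


@pytest.fixture
def nb_dataset():
    """Simulated two-group NB dataset (500 genes, 3 vs 3, phi = 0.05)."""
    ds, truth = cq.simulate.simulate_nb(
        500, 6, group=["A"] * 3 + ["B"] * 3, bcv_trend=np.sqrt(0.05), seed=101
    )
    return ds, truth
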