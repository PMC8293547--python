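import numpy as np
import pandas as pd
import pytest

from hexpov import PovertyLine, row_standardize
from hexpov.synth import generate_lattice_weights


@pytest.fixture
def rook22():
    """Row-standardized 2x2 rook lattice (each cell has two neighbors)."""
    return row_standardize(generate_lattice_weights(2, 2, "rook"))


@pytest.fixture
def line100():
    return PovertyLine(100.0, "test")


@pytest.fixture
def four_records():
    """Four households, one pushed from 120 to 50 by OOP spending of 70."""
    return pd.DataFrame({
        "region_id": ["A"] * 4,
        "income": [120.0, 300.0, 80.0, 500.0],
        "health_exp_total": [100.0, 10.0, 5.0, 20.0],
        "reimbursed": [20.0, 5.0, 0.0, 10.0],
        "expected_reimbursed": [10.0, 0.0, 0.0, 0.0],
    })


def dense_moran(values, W_dense):
    """Naive O(n^2) double-loop Moran's I oracle."""
    x = np.asarray(values, dtype=float)
    n = x.size
    z = x - x.mean()
    s0 = num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += W_dense[i, j]
            num += W_dense[i, j] * z[i] * z[j]
    return n / s0 * num / (z @ z)
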