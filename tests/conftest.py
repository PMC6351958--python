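import numpy as np
import pandas as pd
import pytest

from crashspat import (
    build_chain_weights,
    kaiyang_like_preset,
    simulate_dataset,
    validate_segments,
)


@pytest.fixture
def chain4():
    return build_chain_weights(4)


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        {
            "segment_id": [1, 2, 3],
            "length": [1.0, 2.0, 0.5],
            "curvature": [1.5, 0.0, 3.2],
            "grade": [0.5, 1.1, 0.0],
            "bridge": [0, 1, 0],
            "ramp": [1, 0, 0],
            "aadt": [20000.0, 18000.0, 22000.0],
            "crash_count": [3, 0, 7],
        }
    )
    return validate_segments(df)


@pytest.fixture(scope="session")
def kaiyang_dataset():
    """One corridor-scale synthetic dataset shared across tests."""
    scn = kaiyang_like_preset()
    scn.seed = 11
    return simulate_dataset(scn)


def moran_bruteforce(y, w):
    """O(n^2) double-loop Moran's I, the independent oracle."""
    y = np.asarray(y, dtype=float)
    n = y.size
    ybar = y.mean()
    d = y - ybar
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w.w[i, j] * d[i] * d[j]
            s0 += w.w[i, j]
    return n / s0 * num / (d @ d).item()
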