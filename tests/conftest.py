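import numpy as np
import pytest

from somnet.io import CANONICAL_CHANNELS, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_recording(rng):
    """90 s of 16-channel noise at 100 Hz."""
    data = rng.normal(0.0, 30.0, size=(16, 9000))
    return Recording(channels=list(CANONICAL_CHANNELS), fs=100.0, data=data)


def random_symmetric_matrix(rng, n=16, zero_fraction=0.0):
    """Symmetric nonnegative weight matrix with zero diagonal."""
    w = rng.uniform(0.0, 1.0, size=(n, n))
    if zero_fraction:
        w[rng.uniform(size=(n, n)) < zero_fraction] = 0.0
    w = np.triu(w, k=1)
    return w + w.T


def floyd_warshall_efficiency(w):
    """Brute-force global-efficiency oracle: reciprocal edge lengths and
    exhaustive all-pairs relaxation, independent of the Dijkstra route."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))
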