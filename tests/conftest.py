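import numpy as np
import pytest

from tecgraph.core import EntropyParams, WeightedGraph


@pytest.fixture
def params():
    return EntropyParams()


@pytest.fixture
def barbell():
    """Two unit-weight triangles {0,1,2} and {3,4,5} joined by edge 2-3."""
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
        W[a, b] = W[b, a] = 1.0
    return WeightedGraph(W)


def random_symmetric(rng, n, density=1.0, self_loops=False):
    m = rng.random((n, n)) * (rng.random((n, n)) < density)
    m = np.triu(m, k=0 if self_loops else 1)
    return m + np.triu(m, k=1).T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
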