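import numpy as np
import pytest
import scipy.sparse as sp

from cvxndl.network_data import Network


def net_from_edges(edges, n=None):
    """Build a Network from an edge list (test helper)."""
    edges = list(edges)
    if n is None:
        n = max(max(e) for e in edges) + 1
    A = sp.lil_matrix((n, n), dtype=np.int8)
    for u, v in edges:
        A[u, v] = 1
        A[v, u] = 1
    return Network(adjacency=A.tocsr())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    return net_from_edges([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def single_edge():
    return net_from_edges([(0, 1)])


@pytest.fixture
def toy_graph():
    """Irregular connected 5-node graph (degrees 1..4)."""
    return net_from_edges([(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (2, 3)])


@pytest.fixture
def cycle8():
    """2-regular vertex-transitive graph."""
    return net_from_edges([(i, (i + 1) % 8) for i in range(8)])
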