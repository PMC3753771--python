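import numpy as np
import pytest
from scipy import sparse

from nltvmri.graph import NLGraph, _graph_from_csr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_graph(shape, rng, n_neighbors=4) -> NLGraph:
    """Random symmetric-weight graph for operator tests: every pixel gets a
    ring neighbour (connectivity guarantee) plus random extra edges, weights
    uniform in (0, 1] symmetrized by max."""
    n = shape[0] * shape[1]
    rows = [np.arange(n)]
    cols = [(np.arange(n) + 1) % n]
    for _ in range(n_neighbors - 1):
        rows.append(np.arange(n))
        cols.append(rng.integers(0, n, n))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    keep = rows != cols
    rows, cols = rows[keep], cols[keep]
    data = rng.uniform(0.05, 1.0, rows.size)
    W = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)
    return _graph_from_csr(W, shape)


@pytest.fixture
def small_graph(rng):
    return random_symmetric_graph((6, 6), rng)
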