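import numpy as np
import pytest
import scipy.sparse as sp

from ggmdx import ZeroPattern


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def five_gene_pattern():
    """The 5-variable example network: edges 1-2, 1-4, 2-3, 2-5, 3-4, 3-5,
    4-5; its maximal cliques are {1,2}, {1,4}, {2,3,5}, {3,4,5}
    (0-based: {0,1}, {0,3}, {1,2,4}, {2,3,4})."""
    edges = [(0, 1), (0, 3), (1, 2), (1, 4), (2, 3), (2, 4), (3, 4)]
    A = np.zeros((5, 5))
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return ZeroPattern(sp.csr_matrix(A))


def random_pd_cov(rng, p, n_factor=4):
    """A generic positive definite sample-covariance-like matrix."""
    M = rng.standard_normal((n_factor * p, p))
    return M.T @ M / (n_factor * p)
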