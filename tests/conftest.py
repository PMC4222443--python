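import numpy as np
import pytest

from pmedianrx.distance import DistanceMatrix
from pmedianrx.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240353)


@pytest.fixture
def small_panel():
    """18 cells, 3 well-separated planted groups in both spaces."""
    spec = SyntheticSpec(n_cells=18, K=3, m=40, n=20, seed=11)
    return generate(spec)


def random_distance_matrix(rng, n, n_features=12):
    """A valid 1 - corr distance matrix from random Gaussian profiles."""
    X = rng.normal(size=(n, n_features))
    d = 1.0 - np.clip(np.corrcoef(X), -1, 1)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d)
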