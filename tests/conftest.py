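import numpy as np
import pytest

import grdsr


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic planted-outlier dataset, normalized, with graph."""
    dm = grdsr.generate_synthetic(seed=0)
    X = grdsr.normalize(dm.X)
    graph = grdsr.build_graph(X, k=5)
    return dm, X, graph


@pytest.fixture(scope="session")
def small_dataset():
    """A small instance for fast model-level tests."""
    dm = grdsr.generate_synthetic(
        n_normal=57, n_outlier=3, m=10, latent_dim=2, n_clusters=2, seed=1
    )
    X = grdsr.normalize(dm.X)
    graph = grdsr.build_graph(X, k=5)
    return dm, X, graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
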