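import numpy as np
import pytest

import deepclust as dc


@pytest.fixture(scope="session")
def blob600():
    """The standard 3-blob recovery fixture: 600 samples, 50-dim ambient."""
    return dc.make_blob_dataset(n_per_class=200, n_clusters=3, latent_dim=2,
                                ambient_dim=50, separation=8.0, noise_sd=1.0,
                                seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dense_spec():
    return dc.BackboneSpec(family="dense", layer_sizes=[32], latent_dim=5)


def make_random_cluster_state(rng, n, K, d, spread=2.0):
    """A random latent/centroid configuration and its Q, P."""
    Z = rng.normal(scale=spread, size=(n, d))
    mu = rng.normal(scale=spread, size=(K, d))
    Q = dc.soft_assign(Z, mu)
    P = dc.target_distribution(Q)
    return Z, mu, Q, P
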