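import numpy as np
import pytest

from muncut.data import MultiLayerData, Partition
from muncut.weights import WeightSet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_channel_data(n=60, vars_per_channel=3, channels=3, noise=0.05, seed=0):
    """Three-layer dataset with strong, disjoint regulatory channels.

    Channel j has its own latent subject factor; every variable of the
    channel (one per layer times vars_per_channel) is that factor plus a
    little noise, so within-channel similarity dominates everything else.
    """
    g = np.random.default_rng(seed)
    factors = g.standard_normal((n, channels))
    layers = []
    for _ in range(3):  # P, G, C
        cols = []
        for ch in range(channels):
            for _ in range(vars_per_channel):
                cols.append(factors[:, ch] + noise * g.standard_normal(n))
        layers.append(np.column_stack(cols))
    Z, Y, X = layers
    return MultiLayerData(X=X, Y=Y, Z=Z)


@pytest.fixture(scope="session")
def channel_data():
    return make_channel_data()


@pytest.fixture(scope="session")
def channel_truth(channel_data):
    per_layer = np.repeat(np.arange(3), 3)
    labels = np.concatenate([per_layer] * 3)
    return Partition(labels, channel_data.layer_of(), K=3)


def toy_weightset(m_per_layer=3, strong=0.9, weak=0.01):
    """9-variable WeightSet with three obvious channels.

    Variable i of each layer belongs to channel i; within-channel weights
    are ``strong`` and everything else ``weak``, both within layers and
    across layers.
    """
    q = p = r = m_per_layer
    m = q + p + r

    def within(d):
        W = np.full((d, d), weak)
        np.fill_diagonal(W, 1.0)
        return W

    W_mega = np.zeros((m, m))
    channel = np.tile(np.arange(m_per_layer), 3)
    layer = np.repeat([0, 1, 2], m_per_layer)
    for i in range(m):
        for j in range(m):
            if abs(layer[i] - layer[j]) == 1:  # adjacent layers only (P-G, G-C)
                W_mega[i, j] = strong if channel[i] == channel[j] else weak
    return WeightSet(
        W_C=within(r), W_G=within(p), W_P=within(q), W_mega=W_mega, sigma=1.0
    )


@pytest.fixture(scope="session")
def toy_weights():
    return toy_weightset()
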