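import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_factor_instance(rng, M, S, I):
    """A generic strictly-positive factorization instance (X, W, H)."""
    from nmfnet.classic_nmf import FactorPair

    X = rng.uniform(0.1, 1.0, size=(M, S))
    W = rng.uniform(0.1, 1.0, size=(S, I))
    W /= W.sum(axis=0)
    H = rng.uniform(0.1, 1.0, size=(M, I))
    return X, FactorPair(W=W, H=H)
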