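import numpy as np
import pytest

from incoherence import ContinuousEntropyConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def entropy_cfg():
    return ContinuousEntropyConfig()


def random_simplex(rng, n_states):
    """A random probability vector (flat Dirichlet)."""
    return rng.dirichlet(np.ones(n_states))
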