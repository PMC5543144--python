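import numpy as np
import pytest

from mescgrn import find_equilibria, nh_threshold, serum_model, two_i_model


@pytest.fixture(scope="session")
def serum():
    return serum_model()


@pytest.fixture(scope="session")
def twoi():
    return two_i_model()


@pytest.fixture(scope="session")
def serum_equilibria(serum):
    return find_equilibria(serum)


@pytest.fixture(scope="session")
def threshold(serum):
    return nh_threshold(serum)


@pytest.fixture(scope="session")
def serum_attractor_states(serum_equilibria):
    return [e.state for e in serum_equilibria if e.stable]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
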