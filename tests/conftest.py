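import numpy as np
import pytest

from enmpcn import fixtures


@pytest.fixture(scope="session")
def tetramer():
    return fixtures.toy_tetramer()


@pytest.fixture(scope="session")
def chain3():
    return fixtures.linear_chain(3)


@pytest.fixture(scope="session")
def chain5():
    return fixtures.linear_chain(5)


@pytest.fixture(scope="session")
def two_state_pair():
    return fixtures.make_two_state_pair(angle_deg=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170122)
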