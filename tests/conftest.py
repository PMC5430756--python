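import numpy as np
import pytest

from isosex.fixtures import fixture_isopod_tree, fixture_state_table, prune_outgroups


@pytest.fixture(scope="session")
def isopod_tree():
    """The packaged chronogram with outgroups pruned (24 isopod tips)."""
    return prune_outgroups(fixture_isopod_tree())


@pytest.fixture(scope="session")
def two_state_table():
    return fixture_state_table("two_state")


@pytest.fixture(scope="session")
def three_state_table():
    return fixture_state_table("three_state")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
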