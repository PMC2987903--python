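import pytest
from hypothesis import settings

from symbiomedia.fixtures import make_toy_joint, make_toy_pair
from symbiomedia.milp_common import MilpConfig

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_pair():
    return make_toy_pair()


@pytest.fixture(scope="session")
def toy_joint():
    return make_toy_joint()


@pytest.fixture(scope="session")
def config():
    return MilpConfig()
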