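import numpy as np
import pytest

import helipol as hp


@pytest.fixture(scope="session")
def equal_arm():
    return hp.get_preset("equal_arm")


@pytest.fixture(scope="session")
def fork_3long():
    return hp.get_preset("fork_3long")


@pytest.fixture(scope="session")
def equal_arm_regions(equal_arm):
    return hp.default_region_map(equal_arm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
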