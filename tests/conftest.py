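import numpy as np
import pytest

from wavestate import hex_array, FlowConfig


@pytest.fixture(scope="session")
def geometry():
    return hex_array()


@pytest.fixture(scope="session")
def ring_pairs(geometry):
    return geometry.neighbor_pairs(geometry.ring_channels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flow_cfg():
    return FlowConfig()
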