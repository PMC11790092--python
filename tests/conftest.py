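import numpy as np
import pytest

from berry3d.scene import build_fixture


@pytest.fixture(scope="session")
def orbit_small():
    """The 128x128, 20-frame orbit fixture with exact ground truth."""
    return build_fixture("orbit-small")


@pytest.fixture(scope="session")
def train_tiny():
    """The 64x64, 60-frame training fixture."""
    return build_fixture("train-tiny")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
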