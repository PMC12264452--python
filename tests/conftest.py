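import numpy as np
import pytest

from cerebwm import SimConfig, generate_montage
from cerebwm.stats import channel_adjacency


@pytest.fixture(scope="session")
def montage16():
    return generate_montage(16)


@pytest.fixture(scope="session")
def adjacency16(montage16):
    return channel_adjacency(montage16)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """Desk-scale simulation config used across unit tests."""
    return SimConfig(n_channels=8, n_trials=20, n_rest_segments=10,
                     n_subjects_per_group=3, seed=99)
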