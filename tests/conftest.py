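import numpy as np
import pytest

from fishvr.config import ArenaConfig, LocomotionConfig, PhysicsConfig, TailConfig, TrialConfig


@pytest.fixture
def arena():
    return ArenaConfig()


@pytest.fixture
def trial_cfg():
    return TrialConfig()


@pytest.fixture
def phys_cfg():
    return PhysicsConfig()


@pytest.fixture
def loco_cfg():
    return LocomotionConfig()


@pytest.fixture
def tail_cfg():
    return TailConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
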