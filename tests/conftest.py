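import numpy as np
import pytest

import asfm3d as a


@pytest.fixture(scope="session")
def scheme():
    return a.default_scheme()


@pytest.fixture(scope="session")
def protocol():
    return a.default_protocol()


@pytest.fixture(scope="session")
def healthy_session():
    """Noise-free, motionless-head, fully symmetric synthetic capture."""
    traj, truth = a.simulate_session(a.SimulationConfig(severity=0.0, noise_sd_mm=0.0))
    return traj, truth


def make_session(**kw):
    cfg = a.SimulationConfig(**kw)
    return a.simulate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
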