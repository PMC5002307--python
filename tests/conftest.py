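import numpy as np
import pytest

from vpcsim import Arena, FiringParams, generate_landmark_field


@pytest.fixture(scope="session")
def arena():
    return Arena(40.0, 40.0)


@pytest.fixture(scope="session")
def baseline_field(arena):
    return generate_landmark_field(arena, 100, "equal", seed=7)


@pytest.fixture(scope="session")
def baseline_params():
    return FiringParams(sigma_d2=25.0, sigma_theta2=100.0, w_d=1, w_theta=1, frt=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
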