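import numpy as np
import pytest

import shbdecay as sd


@pytest.fixture(scope="session")
def shb_surface():
    """The natural short-hydrogen-bond surface (2.5 A, defaults)."""
    return sd.build_surface(2.5)


@pytest.fixture(scope="session")
def shb_ground_long(shb_surface):
    """Long (25 ps) thermostatted ground sampling at the short bond; shared
    by the free-energy and descriptor tests."""
    return sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 50_000, seed=11)


@pytest.fixture(scope="session")
def excited_1ps():
    """A 1 ps excited-state trajectory at an intermediate bond length."""
    surface = sd.build_surface(3.5)
    ground = sd.sample_ground_trajectory(surface, 300.0, 0.5, 6000, seed=1)
    return sd.run_excited_trajectory(surface, ground.frame(-1), 1000.0, 0.5,
                                     seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
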