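import numpy as np
import pytest

from psfglm import ArenaSpec, build_basis, simulate_trajectory


@pytest.fixture(scope="session")
def basis():
    return build_basis()


@pytest.fixture(scope="session")
def arena():
    return ArenaSpec()


@pytest.fixture(scope="session")
def traj900(arena):
    """One 15-min foraging session shared across tests."""
    return simulate_trajectory(arena, duration=900.0, mean_speed=15.0, seed=1)


@pytest.fixture(scope="session")
def traj120(arena):
    return simulate_trajectory(arena, duration=120.0, mean_speed=15.0, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
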