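import numpy as np
import pytest

from beammatch.config import BeamLineConfig, GantryPerturbation
from beammatch.idd import build_basis
from beammatch.physics import default_depth_grid
from beammatch.synthetic import simulate_idd


@pytest.fixture(scope="session")
def config():
    return BeamLineConfig()


@pytest.fixture(scope="session")
def depth_grid(config):
    return default_depth_grid(config)


@pytest.fixture(scope="session")
def basis_150(config, depth_grid):
    """41-member pristine basis around 150 MeV on the default grid."""
    return build_basis(150.0, depth_grid, config)


@pytest.fixture(scope="session")
def noisy_idd_150(config):
    """A noisy synthetic measured curve at 150 MeV (sigma_E = 1.05 MeV)."""
    pert = GantryPerturbation(dose_noise=0.002)
    return simulate_idd(150.0, 0.007 * 150.0, pert, config, rng=7)
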