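import numpy as np
import pytest

from nanocg import fixtures as fx
from nanocg import forcefield as ff


@pytest.fixture(scope="session")
def params():
    return ff.default_params()


@pytest.fixture(scope="session")
def np_fixture():
    """Default synthetic NP reference trajectory with its ground truth."""
    return fx.make_np_reference_trajectory(n_frames=500, r_outer=8.0,
                                           jitter_std=0.8, tumble=True, seed=11)


@pytest.fixture(scope="session")
def small_protein():
    return fx.make_toy_protein(24, seed=7)


@pytest.fixture(scope="session")
def ms_np():
    return fx.make_ms_np_body()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def inert_params(n_species=1, cutoff=30.0):
    """Parameter set with interaction-free species, for free-diffusion tests."""
    species = {
        f"X{k}": ff.Species(name=f"X{k}", sigma=5.0, epsilon=0.0, hindex=0.0,
                            charge=0.0, mass=1.0)
        for k in range(n_species)
    }
    return ff.FFParams(species=species, debye_length=17.6, cutoff=cutoff)
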