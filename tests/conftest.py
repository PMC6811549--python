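import numpy as np
import pytest

from spinequant.cohort import generate_cohort
from spinequant.simulate import NeuronParams


@pytest.fixture(scope="session")
def small_cohort():
    """Two animals per genotype, one cell each, light protocols."""
    return generate_cohort(n_animals=2, cells_per_animal=1,
                           protocols=("steps", "uncage_seq"), seed=7)


@pytest.fixture()
def passive_params():
    """Single-compartment passive membrane: R = 150 MOhm, tau = 15 ms."""
    return NeuronParams(cm=100.0, g_leak=1000.0 / 150.0, e_leak=-65.0,
                        g_hcn_max=0.0, compartments=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
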