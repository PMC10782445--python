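import numpy as np
import pytest

from redoxcb import SyntheticWorkSpec, WorkSet, generate_crooks_gaussian, make_thermo
from redoxcb.thermo import BOLTZMANN_KJ_PER_MOL_K


@pytest.fixture(scope="session")
def thermo298():
    return make_thermo(298.0)


@pytest.fixture(scope="session")
def unit_thermo():
    """ThermoState with k_B·T = 1 kJ/mol, so β = 1 and work is in kT units."""
    return make_thermo(1.0 / BOLTZMANN_KJ_PER_MOL_K)


@pytest.fixture
def single_pair_ws(unit_thermo):
    """One forward work value +2, one backward −2: everything symmetric about 2."""
    return WorkSet([2.0], [-2.0], unit_thermo)


@pytest.fixture(scope="session")
def gaussian_ws():
    """Crooks-exact Gaussian WorkSet, ΔG_true = 5, σ = 2, n = 2000/side."""
    return generate_crooks_gaussian(SyntheticWorkSpec(5.0, 2.0, 2000, 298.0, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
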