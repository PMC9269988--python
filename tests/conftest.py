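import numpy as np
import pytest

from tcatsim import SpeciesTable, ThermoParams
from tcatsim.fixtures import default_species_table, two_phase_phases


@pytest.fixture(scope="session")
def table() -> SpeciesTable:
    return default_species_table()


@pytest.fixture(scope="session")
def phases():
    return two_phase_phases()


@pytest.fixture(scope="session")
def thermo() -> ThermoParams:
    return ThermoParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
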