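import pytest
from hypothesis import settings

from phytoextract import SimulationConfig, SoilCompartment, load_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# the study compartment: 1 m^2, 0.35 m deep, 1500 kg/m^3, 10 -> 1 mg/kg dw
SOIL = SoilCompartment(c_soil_i=10.0, c_soil_f=1.0)


@pytest.fixture(scope="session")
def soil():
    return SOIL


@pytest.fixture(scope="session")
def literature():
    return load_dataset("literature")


@pytest.fixture(scope="session")
def site_specific():
    return load_dataset("site_specific")


@pytest.fixture(scope="session")
def literature_config(literature):
    return SimulationConfig(soil=SOIL, input_specs=literature.specs(), seed=1)


@pytest.fixture(scope="session")
def site_config(site_specific):
    return SimulationConfig(soil=SOIL, input_specs=site_specific.specs(), seed=1)
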