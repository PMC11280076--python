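import pytest
from hypothesis import HealthCheck, settings

import ocupbpk as o

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def drug():
    return o.besifloxacin()


@pytest.fixture(scope="session")
def rabbit():
    return o.builtin_physiology("NZ_rabbit")


@pytest.fixture(scope="session")
def human():
    return o.builtin_physiology("human")


@pytest.fixture(scope="session")
def mixed_form(drug):
    return o.besivance_mixed_cr(drug)


@pytest.fixture(scope="session")
def susp_form(drug):
    return o.besivance_suspension(drug)


@pytest.fixture(scope="session")
def single_dose(mixed_form):
    """The reference protocol: one 50 µL drop of 0.6% suspension at t = 0."""
    return [o.DoseEvent(time=0.0, volume=50.0, strength=6.0, formulation=mixed_form)]


@pytest.fixture(scope="session")
def rabbit_single_sim(drug, mixed_form, rabbit, single_dose):
    """Reference 24 h rabbit simulation, shared across tests."""
    return o.simulate(drug, mixed_form, rabbit, single_dose, 24.0)
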