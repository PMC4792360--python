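import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_spec():
    from acosim.population import make_default_population_fixture
    return make_default_population_fixture()


@pytest.fixture(scope="session")
def default_params():
    from acosim.disease import default_transition_parameters
    return default_transition_parameters()


@pytest.fixture
def chf_patient():
    """A CHF-diagnosed 80-year-old used across transition tests."""
    from acosim.population import PatientProfile
    return PatientProfile(
        id=0, age=80, age_group=4, race="white", gender="female", income="middle",
        has_diabetes=True, has_hypertension=True, has_chf=True,
        chf_dx_source="outpatient")


def small_config(**overrides):
    """A reduced-scale simulation config for fast integration tests."""
    from acosim.engine import SimulationConfig
    defaults = dict(n_patients=1000)
    defaults.update(overrides)
    return SimulationConfig(**defaults)
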