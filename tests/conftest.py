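import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from topochrom import UnitSystem, model


@pytest.fixture(scope="session")
def units_default():
    return UnitSystem.from_conditions()


@pytest.fixture(scope="session")
def mono_diameter(units_default):
    """Monodisperse bead diameter in l units."""
    return units_default.to_l(50.5086)


@pytest.fixture(scope="session")
def small_params():
    """Small passive monodisperse system for engine tests."""
    return model.monodisperse_params(N=64, phi_A=0.5, eps_hc=0.0, lambda_ra=0.0,
                                     variant="PASSIVE")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
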