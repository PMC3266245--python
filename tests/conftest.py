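import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fmafm.dynamics import liquid_preset, single_mode_preset
from fmafm.forces import (ForceModel, TipGeometry, ContactMaterial,
                          default_approach_model)


@pytest.fixture(scope="session")
def cantilever():
    """Two-mode liquid preset (19 kHz, 0.6 N/m)."""
    return liquid_preset()


@pytest.fixture(scope="session")
def single_mode():
    return single_mode_preset()


@pytest.fixture(scope="session")
def approach_model():
    """Stiff substrate with the shipped solvation calibration."""
    return default_approach_model()


@pytest.fixture(scope="session")
def contact_model():
    """Contact-only rigid substrate (no solvation)."""
    return ForceModel(tip=TipGeometry(10.0),
                      material=ContactMaterial(elastic_modulus=1e10))


@pytest.fixture
def rng():
    return np.random.default_rng(20260214)
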