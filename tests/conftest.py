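import numpy as np
import pytest
from hypothesis import settings

from phaselag import Environment, Nanoprobe, OperatingPoint

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def probe() -> Nanoprobe:
    """Reference probe: 400x200 nm ellipse, 7 nm NiFe in a 60 nm stack,
    measured anisotropy field 30 mT, hydrodynamic envelope factor 3."""
    return Nanoprobe()


@pytest.fixture
def env() -> Environment:
    """Water at room temperature."""
    return Environment()


@pytest.fixture
def op500() -> OperatingPoint:
    """Mid-curve operating point: 500 Hz drive at 10 mT."""
    return OperatingPoint.from_frequency(500.0, 10e-3)


@pytest.fixture
def rigid_probe() -> Nanoprobe:
    """Probe with an enormous anisotropy field: magnetization locked to the
    easy axis, so the measured lag reduces to the viscous lag."""
    return Nanoprobe(mu0_Hk_T=1.0e6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
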