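import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from soxdosim.soed import IrradiationProtocol, PhantomSpec, SOEDParameters
from soxdosim.synthetic import BasisShapeConfig, make_basis

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def basis():
    """Default NIR basis (o2 / phosphorescence / background) on 1200-1600 nm."""
    return make_basis(BasisShapeConfig())


@pytest.fixture
def protocol():
    """Standard irradiation: 850 mW/cm2 for 900 s, acquisitions every 100 s."""
    return IrradiationProtocol()


@pytest.fixture
def phantom6():
    """6 mg/L phantom with clamped oxygen at 194 uM."""
    return PhantomSpec(bpd_mg_per_L=6.0)


@pytest.fixture
def params():
    return SOEDParameters()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
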