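import numpy as np
import pytest

from hetpop import DimensionlessParams, build_constants
from hetpop.cnmc import DivisionModel


@pytest.fixture(scope="session")
def constants():
    """Default kinetic constants with calibrated transport rate."""
    return build_constants()


@pytest.fixture(scope="session")
def params_fig7():
    """Dimensionless parameters at the rho = 0.09 reference point."""
    return DimensionlessParams(pi=0.03, rho=0.09, kappa=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def symmetric_division():
    return DivisionModel(m=2.0, f=0.5)
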