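import numpy as np
import pytest

from isoflux import EnergeticIsoParams, LeafEnvironment, PhotoParams


@pytest.fixture(scope="session")
def reference_photo() -> PhotoParams:
    """The headline leaf: Vcmax25 = 70, Jmax25 = 130, low Rd."""
    return PhotoParams(vcmax25=70.0, jmax25=130.0, rd25=0.5)


@pytest.fixture(scope="session")
def reference_env() -> LeafEnvironment:
    """Standard operating point: T = 30 degC, ci = 273, PAR = 1000."""
    return LeafEnvironment(par_absorbed=1000.0, t_leaf=30.0, ci=273.0)


@pytest.fixture(scope="session")
def iso_params() -> EnergeticIsoParams:
    return EnergeticIsoParams(a=0.3, b=0.1)


@pytest.fixture(scope="session")
def par_grid():
    return np.arange(0.0, 2000.1, 10.0)


@pytest.fixture(scope="session")
def ci_grid():
    return np.arange(20.0, 801.0, 20.0)
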