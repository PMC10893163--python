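import numpy as np
import pytest

from vbesim import CompoundParams, DosingRegimen, WeibullParams
from vbesim.dissolution import USP_TIMES


@pytest.fixture(scope="session")
def usp_times():
    return np.array(USP_TIMES)


@pytest.fixture(scope="session")
def mr_release():
    """Modified-release Weibull profile used across PK tests."""
    return WeibullParams(fmax=92.0, lag=0.5, alpha=9.0, beta=1.15)


@pytest.fixture(scope="session")
def simple_compound():
    """One-compartment compound with round numbers (CL_total = 9 L/h)."""
    return CompoundParams(
        volume_of_distribution=50.0, clint_total=10.0, ka=2.0,
        fu_plasma=1.0, hepatic_blood_flow=90.0, renal_cl=0.0,
    )


@pytest.fixture(scope="session")
def single_dose():
    return DosingRegimen.single(2.0)


@pytest.fixture(scope="session")
def dense_grid():
    return np.linspace(0.0, 120.0, 120 * 8 + 1)
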