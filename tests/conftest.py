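import numpy as np
import pytest

from patternlab.grid import GridSpec
from patternlab.models.brusselator import BrusselatorParams
from patternlab.models.cortical import CorticalParams


@pytest.fixture
def grid1d():
    return GridSpec(ndim=1, npoints=(60,), spacing=1.0)


@pytest.fixture
def grid2d():
    return GridSpec(ndim=2, npoints=(24, 24), spacing=1.0)


@pytest.fixture
def brusselator_turing_params():
    """Activator slow, inhibitor fast: stationary-pattern regime."""
    return BrusselatorParams(A=2.0, B=4.8, D_X=2.0, D_Y=10.0)


@pytest.fixture
def brusselator_hopf_params():
    """Oscillatory regime: excited q = 0 mode."""
    return BrusselatorParams(A=2.5, B=9.0, D_X=7.0, D_Y=10.0)


@pytest.fixture(scope="session")
def reference_record():
    """Swept cortical reference configuration (computed once per session)."""
    from patternlab.reference import sweep_reference_configuration

    best, records = sweep_reference_configuration()
    return best


@pytest.fixture(scope="session")
def reference_setup(reference_record):
    """(params, steady_state) of the recorded reference configuration."""
    from patternlab.linstab import steady_states

    params = reference_record.params()
    states = steady_states("cortical", params)
    ss = min(states,
             key=lambda s: abs(s.values["V_e"] - reference_record.branch_Ve))
    return params, ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
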