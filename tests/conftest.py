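import numpy as np
import pytest
from hypothesis import settings

from diffsens.models import ODEModel

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def decay_model():
    """Pure exponential decay dI/dt = -delta*I with a known solution."""
    return ODEModel(
        name="decay",
        state_names=("I",),
        param_names=("delta",),
        rhs=lambda x, p, t: np.array([-p[0] * x[0]]),
        default_params=np.array([0.5]),
        default_x0=np.array([100.0]),
        default_tspan=(0.0, 10.0),
    )


@pytest.fixture
def two_node_process():
    """Two-node birth-death-migration process with hand-checkable rates."""
    from diffsens.branching import BDMProcess

    return BDMProcess(
        beta=[1.5, 1.5], delta=[1.0, 1.75], lam=[[0.0, 0.5], [1.0, 0.0]]
    )
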