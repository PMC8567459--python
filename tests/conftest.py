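import numpy as np
import pytest

from refreshcat.components import build_component_set
from refreshcat.distributions import CRPParams
from refreshcat.model import Hyperparameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hyper2():
    """Trained-approximation hyperparameters in two dimensions."""
    return Hyperparameters(
        dim=2, crp=CRPParams(alpha=10.0, alpha_c=0.001, alpha_g=0.0),
        sigma_r2=0.1, omega=np.zeros(2))


@pytest.fixture
def hyper2_untrained():
    """Full-hierarchy hyperparameters in two dimensions."""
    return Hyperparameters(
        dim=2, crp=CRPParams(alpha=10.0, alpha_c=0.001, alpha_g=1.0),
        v_t=30.0, sigma_r2=1.0, omega=np.zeros(2))


@pytest.fixture
def cset_nw_wn():
    return build_component_set(("nw", "wn"), (1.0, 1.0))
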