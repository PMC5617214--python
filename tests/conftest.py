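import numpy as np
import pytest

from fhrhdp import hdpgmm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scalar_prior():
    """Small hand-set 1-D Normal–Inverse-Wishart prior used by the oracles."""
    return hdpgmm.NIWPrior(mu0=np.array([0.5]), kappa0=2.0, nu0=3.0,
                           psi0=np.array([[1.5]]))
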