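import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("repro", derandomize=True, deadline=None)
_hyp_settings.load_profile("repro")

from tadmri import (
    CordPhantomConfig,
    alpha_protocol,
    dti_protocol,
    gamma_protocol,
    make_cord_phantom,
    qsi_protocol,
)


@pytest.fixture(scope="session")
def gamma_proto():
    return gamma_protocol()


@pytest.fixture(scope="session")
def alpha_proto():
    return alpha_protocol()


@pytest.fixture(scope="session")
def dti_proto():
    return dti_protocol()


@pytest.fixture(scope="session")
def qsi_proto():
    return qsi_protocol()


@pytest.fixture(scope="session")
def cord_phantom():
    """Small deterministic cord phantom shared across tests."""
    return make_cord_phantom(CordPhantomConfig(shape=(1, 32, 32),
                                               capillary_radius=15.0,
                                               cord_radius=11.0,
                                               gm_radius=5.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
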