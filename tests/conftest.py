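import numpy as np
import pytest

from microfit.models import make_model
from microfit.protocols import AcquisitionProtocol
from microfit.synthetic import protocol_preset

#: typical ex vivo white-matter ground truth for the cylinder model
EXVIVO_GT = {"da": 2.0, "fia": 0.7, "fdot": 0.15,
             "dpara": 0.6, "dperp_frac": 0.3}


@pytest.fixture(scope="session")
def dt15_protocol():
    """Ex vivo multi-b protocol, δ/Δ = 11/15.192 ms, b up to 43."""
    return protocol_preset("excaliber_exvivo_dt15")


@pytest.fixture(scope="session")
def hcp_protocol():
    return protocol_preset("hcp_smt")


@pytest.fixture(scope="session")
def excaliber():
    return make_model("ExCaliber")


@pytest.fixture(scope="session")
def smt():
    return make_model("SMT")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def simple_protocol():
    """Small shell protocol with PGSE timings for compartment tests."""
    b = np.array([0.0, 1.0, 2.5, 5.0, 18.1, 43.0])
    n = b.size
    return AcquisitionProtocol(bval=b, tdelta=np.full(n, 15.192),
                               tsmalldel=np.full(n, 11.0))
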