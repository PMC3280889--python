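import numpy as np
import pytest
from hypothesis import settings

from nfdelay import make_ring_model

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

REF_COEFFS = [(0, -1.0), (2, 1.5)]


@pytest.fixture(scope="session")
def ref_coeffs():
    """Kernel of the reference ring model: J(z) = -1 + 1.5 cos(2z)."""
    return list(REF_COEFFS)


@pytest.fixture(scope="session")
def ring_factory(ref_coeffs):
    """Reference scalar ring model at a requested (c, sigma)."""

    def make(c=1.0, sigma=1.0, n=48, **kw):
        return make_ring_model(ref_coeffs, c=c, sigma=sigma, n=n, **kw)

    return make


@pytest.fixture(scope="session")
def sigma0():
    """Closed-form pitchfork gain of the reference model: l/(s1 * 1.5*pi)."""
    return 8.0 / (3.0 * np.pi)
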