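import numpy as np
import pytest

from ssnvar.architectures import (
    MultiAttractorParams,
    RingGeometry,
    build_multiattractor,
    build_ring,
    build_two_pop,
)


@pytest.fixture(scope="session")
def two_pop():
    """Reduced two-population SSN with its table noise covariance."""
    return build_two_pop()


@pytest.fixture(scope="session")
def ring():
    """Ring SSN (50 E + 50 I) with its table noise covariance."""
    geo = RingGeometry()
    net, noise = build_ring(geo)
    return geo, net, noise


@pytest.fixture(scope="session")
def multiattractor():
    params = MultiAttractorParams()
    net, noise = build_multiattractor(params)
    return params, net, noise


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
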