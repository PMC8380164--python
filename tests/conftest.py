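import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from paareg import PhantomSpec, make_phantom

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_phantom():
    """The default 64-cube asymmetric registration phantom."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """A 32-cube asymmetric phantom for fast registration tests."""
    return make_phantom(PhantomSpec(shape=(32, 32, 32)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
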