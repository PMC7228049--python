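import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dwimarkers.phantom import PhantomSpec, default_scheme, make_atlas
from dwimarkers.signature import default_library

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: fixed seed for every stochastic fixture/test in the suite
SEED = 20260930


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture
def small_spec():
    """Noiseless phantom on a reduced grid, no effect — fast unit fixture."""
    return PhantomSpec(seed=SEED, grid_shape=(16, 16, 6), snr=None)


@pytest.fixture
def small_noisy_spec():
    return PhantomSpec(seed=SEED, grid_shape=(16, 16, 6), snr=40.0)


@pytest.fixture
def small_atlas(small_spec):
    return make_atlas(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
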