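import numpy as np
import pytest

from csfmotion import PhantomGeometry, make_phantom_masks
from csfmotion.dwi import DEFAULT_BVALUES


@pytest.fixture(scope="session")
def bvalues():
    return np.asarray(DEFAULT_BVALUES)


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry(shape=(64, 64, 28))


@pytest.fixture(scope="session")
def small_geometry():
    return PhantomGeometry(shape=(32, 32, 14))


@pytest.fixture(scope="session")
def masks(geometry):
    return make_phantom_masks(geometry, seed=7)


@pytest.fixture(scope="session")
def small_masks(small_geometry):
    return make_phantom_masks(small_geometry, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240509)
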