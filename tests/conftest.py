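import numpy as np
import pytest

from saseg.phantomgen import PhantomParams, make_mandible_phantom, make_population
from saseg.volio import BinaryMask, Volume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def phantom_params():
    """Default-family phantom at the package's standard test grid."""
    return PhantomParams()


@pytest.fixture(scope="session")
def phantom_pair(phantom_params):
    return make_mandible_phantom(phantom_params, seed=5)


@pytest.fixture(scope="session")
def phantom_population(phantom_params):
    return make_population(6, phantom_params, seed=7)


@pytest.fixture()
def sphere_mask():
    """Radius-8-voxel sphere at unit spacing."""
    shape = (24, 24, 24)
    c = np.asarray(shape) / 2 - 0.5
    idx = np.indices(shape)
    r2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
    return BinaryMask((r2 < 64).astype(np.uint8), (1.0, 1.0, 1.0))


def random_mask(rng, shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0), p=0.3):
    """Small random blob mask guaranteed non-empty."""
    data = (rng.random(shape) < p).astype(np.uint8)
    if not data.any():
        data[tuple(s // 2 for s in shape)] = 1
    return BinaryMask(data, spacing)
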