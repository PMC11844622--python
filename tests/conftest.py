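import numpy as np
import pytest

from mrimoco.kspace import ImageSlice
from mrimoco.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom64():
    return generate_phantom(PhantomSpec(size=64, seed=3))


@pytest.fixture
def phantom128():
    return generate_phantom(PhantomSpec(size=128, seed=3))


@pytest.fixture
def random_image(rng):
    return ImageSlice(rng.random((32, 32)))
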