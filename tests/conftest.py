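import numpy as np
import pytest

from pgchmm.fixtures import PhantomSpec, generate_phantom
from pgchmm.grid import ImageGrid


@pytest.fixture(scope="session")
def phantom_128():
    return generate_phantom(PhantomSpec(size=(128, 128), seed=7))


@pytest.fixture(scope="session")
def phantom_256():
    return generate_phantom(PhantomSpec(size=(256, 256), seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def random_image_64():
    rng = np.random.default_rng(99)
    return ImageGrid(rng.random((64, 64)), "unit")
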