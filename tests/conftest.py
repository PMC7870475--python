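import numpy as np
import pytest
from hypothesis import settings

from classimage import BasisConfig, build_basis, make_template

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

TINY_CONFIG = BasisConfig(
    image_size=16,
    scales=(2, 4),
    grid_dims=(1, 2),
    orientations=(0.0, 60.0, 120.0),
    phases=(0.0, np.pi / 2),
)


@pytest.fixture(scope="session")
def tiny_basis():
    """30-parameter basis: scales (2, 4), 3 orientations, 2 phases, 16 px."""
    return build_basis(TINY_CONFIG)


@pytest.fixture(scope="session")
def small_basis():
    """Full default structure (K = 4092) at a desk-size 64 px image."""
    return build_basis(BasisConfig(image_size=64))


@pytest.fixture(scope="session")
def tiny_template(tiny_basis):
    return make_template(tiny_basis.image_size, style="flat")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
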