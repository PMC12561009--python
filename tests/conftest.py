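import numpy as np
import pytest

from gamsunet.io_preprocess import ImageVolume, MaskVolume
from gamsunet.network import NetworkConfig
from gamsunet.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic phantom subject (image, mask)."""
    return generate_phantom(PhantomConfig(), seed=42)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest GA-MS config exercising every block type."""
    return NetworkConfig(depth=2, widths=(4, 8), gn_groups=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_volume():
    vox = np.arange(4 * 4 * 4, dtype=np.float64).reshape(4, 4, 4)
    return ImageVolume(vox, (0.7, 0.7, 0.7), np.diag([0.7, 0.7, 0.7, 1.0]), "toy")


def make_mask(labels, spacing=(0.7, 0.7, 0.7)):
    labels = np.asarray(labels, dtype=np.uint8)
    return MaskVolume(labels, spacing, np.diag(list(spacing) + [1.0]), "toy")
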