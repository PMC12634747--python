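import numpy as np
import pytest

from maskscope.synthetic_cohort import (
    AcquisitionConfig,
    default_cohort_config,
    generate_texture,
    make_phantom,
)


@pytest.fixture(scope="session")
def small_acq():
    """128x128 raster at 0.4 mm pitch: fast but geometrically faithful."""
    return AcquisitionConfig(image_shape=(128, 128), pixel_pitch=0.4)


@pytest.fixture(scope="session")
def small_config():
    return default_cohort_config(12, 12, seed=11, image_size="small")


@pytest.fixture(scope="session")
def phantom_83(small_acq):
    """Phantom calibrated to the interval-group median VBD of 8.3%."""
    tex = generate_texture(small_acq.image_shape, small_acq.beta, 1.0, seed=5)
    return make_phantom(small_acq, 8.3, tex)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
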