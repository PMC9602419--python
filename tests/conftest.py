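import numpy as np
import pytest

from ciea import SynthConfig, generate_dataset


# 4x4 coefficient matrix used throughout the contrast-boost tests; its
# min (1.0) and max (254.2) must be fixed points of the remap.
EXAMPLE_MATRIX = np.array(
    [
        [11.3, 254.2, 1.0, 2.3],
        [19.6, 200.1, 221.9, 230.6],
        [5.8, 9.7, 6.1, 210.9],
        [219.3, 228.2, 8.8, 236.8],
    ]
)


@pytest.fixture
def example_matrix():
    return EXAMPLE_MATRIX.copy()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """40 small noiseless-ish images, both classes present."""
    return generate_dataset(
        SynthConfig(image_size=32, n_images=40, noise_sigma=0.02, seed=7)
    )


@pytest.fixture(scope="session")
def lung_image():
    """One synthetic negative-class lung image at 64x64."""
    ds = generate_dataset(SynthConfig(image_size=64, n_images=2, seed=3))
    return next(im.pixels for im in ds if im.label == 0)
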