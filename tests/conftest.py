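import numpy as np
import pytest
from skimage import color as skcolor

from camokit import CategorySpec, RasterImage, generate_background_bank


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def lab_image(L, a=0.0, b=0.0, image_id="lab"):
    """Build an sRGB RasterImage from an L* field and constant chroma."""
    L = np.asarray(L, float)
    lab = np.zeros((*L.shape, 3))
    lab[..., 0] = L
    lab[..., 1] = a
    lab[..., 2] = b
    return RasterImage(np.clip(skcolor.lab2rgb(lab), 0, 1), image_id=image_id)


def sinusoid_image(size, wavelength, amplitude, mean_l=50.0, image_id="sin"):
    """Horizontal L* sinusoid of a given wavelength (pixels) and amplitude."""
    x = np.arange(size)
    L = mean_l + amplitude * np.sin(2 * np.pi * x / wavelength)
    return RasterImage(
        np.clip(
            skcolor.lab2rgb(
                np.dstack(
                    [
                        np.tile(L, (size, 1)),
                        np.zeros((size, size)),
                        np.zeros((size, size)),
                    ]
                )
            ),
            0,
            1,
        ),
        image_id=image_id,
    )


def random_image(rng, h=64, w=64, image_id="rand", lo=0.0, hi=1.0):
    return RasterImage(
        lo + (hi - lo) * rng.random((h, w, 3)), image_id=image_id
    )


@pytest.fixture(scope="session")
def mini_bank():
    """A small two-category bank large enough to cut 150x75 targets from."""
    specs = (
        CategorySpec("dark", (35.0, 5.0, 10.0), (2.0, 1.0, 1.0), 1.6, 8.0, 0.0),
        CategorySpec("light", (65.0, -10.0, 20.0), (2.0, 1.0, 1.0), 1.2, 12.0, 0.0),
    )
    return generate_background_bank(specs, 4, 192, 192, seed=777)
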