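import numpy as np
import pytest

from slbphase import SceneParams, gen_bilayer_image
from slbphase.imgproc import RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def nucleated_scene():
    """A clean nucleated scene (no noise, no offset) with its ground truth."""
    params = SceneParams(
        width=256,
        height=256,
        morphology="nucleated",
        noise_sd=0.0,
        camera_offset=0.0,
        seed=7,
    )
    img, mask = gen_bilayer_image(params)
    return params, img, mask


def make_image(values, pixel_size=0.16):
    return RasterImage(values=np.asarray(values, dtype=float), pixel_size=pixel_size)
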