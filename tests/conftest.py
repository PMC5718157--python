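import numpy as np
import pytest

import dopplerwss as dw
from dopplerwss.velocity_decode import BACKGROUND, PixelMask, VelocityField


@pytest.fixture(scope="session")
def classic_cmap():
    return dw.load_colormap("red-blue-brightness")


@pytest.fixture(scope="session")
def fine_cmap():
    return dw.load_colormap("red-blue-fine")


@pytest.fixture(scope="session")
def default_phantom(fine_cmap):
    """Noise-free laminar phantom at the default spacing R/100."""
    spec = dw.PhantomSpec(n_columns=64)
    frame, truth = dw.generate_poiseuille_frame(spec, fine_cmap)
    return spec, frame, truth


@pytest.fixture(scope="session")
def decoded_phantom(default_phantom, fine_cmap):
    spec, frame, truth = default_phantom
    mask = dw.classify_pixels(frame)
    field, report = dw.decode_velocity(frame, fine_cmap, mask)
    return spec, frame, truth, mask, field, report


def pad_square(field: VelocityField, mask: PixelMask, size: int):
    """Embed a field/mask pair centered in a size x size background canvas
    (rotation tests need room so the content is not clipped)."""
    h, w = mask.shape
    if size < max(h, w):
        raise ValueError("canvas smaller than content")
    labels = np.full((size, size), BACKGROUND, dtype=np.uint8)
    v = np.zeros((size, size))
    valid = np.zeros((size, size), dtype=bool)
    r0, c0 = (size - h) // 2, (size - w) // 2
    labels[r0 : r0 + h, c0 : c0 + w] = mask.labels
    v[r0 : r0 + h, c0 : c0 + w] = field.v
    valid[r0 : r0 + h, c0 : c0 + w] = field.valid
    return (
        VelocityField(v, valid, field.spacing_axial, field.spacing_lateral),
        PixelMask(labels),
    )
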