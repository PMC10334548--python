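import numpy as np
import pytest

from cmtkit.stack_io import PlanarImage
from cmtkit.segmentation_roi import LabelImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def grid_label_image(n_rows=3, n_cols=3, cell_px=30, wall_px=1, pixel_size_um=1.0):
    """Labelled cell grid with `wall_px`-wide 0-lines between labels."""
    pitch = cell_px + wall_px
    h = n_rows * pitch + wall_px
    w = n_cols * pitch + wall_px
    labels = np.zeros((h, w), dtype=np.int32)
    lid = 0
    for i in range(n_rows):
        for j in range(n_cols):
            lid += 1
            r0 = i * pitch + wall_px
            c0 = j * pitch + wall_px
            labels[r0 : r0 + cell_px, c0 : c0 + cell_px] = lid
    return LabelImage(labels, pixel_size_um)


def grid_contour_image(n_rows=3, n_cols=3, cell_px=30, wall_px=2, pixel_size_um=1.0,
                       noise_sd=0.0, seed=0, margin_px=0):
    """Bright-walled cell contour image matching grid_label_image geometry.

    ``margin_px`` adds a dark frame outside the outer walls, giving the
    watershed a background basin.
    """
    pitch = cell_px + wall_px
    h = n_rows * pitch + wall_px
    w = n_cols * pitch + wall_px
    img = np.ones((h, w))
    for i in range(n_rows):
        for j in range(n_cols):
            r0 = i * pitch + wall_px
            c0 = j * pitch + wall_px
            img[r0 : r0 + cell_px, c0 : c0 + cell_px] = 0.05
    if margin_px:
        img = np.pad(img, margin_px, constant_values=0.05)
    if noise_sd:
        img = img + np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    return PlanarImage(np.clip(img, 0, None), pixel_size_um, kind="contour")


def disk_mask(dims=(128, 128), center=None, radius=10.0):
    h, w = dims
    cy, cx = center if center else ((h - 1) / 2, (w - 1) / 2)
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
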