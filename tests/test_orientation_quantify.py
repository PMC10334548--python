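import math

import numpy as np
import pytest
from skimage.transform import rotate

from cmtkit.orientation_quantify import nematic_tensor, quantify_rois, render_quantification
from cmtkit.segmentation_roi import CellROISet
from cmtkit.stack_io import PlanarImage
from cmtkit.synthetic_data import make_texture


def full_mask(dims):
    return np.ones(dims, dtype=bool)


class TestNematicTensor:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 60.0, 89.0])
    def test_stripe_orientation_recovered_within_one_degree(self, angle):
        img = make_texture((64, 64), angle, wavelength_px=8)
        m = nematic_tensor(img, full_mask((64, 64)))
        assert m.valid
        diff = (m.angle_deg - angle + 90) % 180 - 90
        assert abs(diff) < 1.0
        assert m.anisotropy > 0.95

    def test_constant_image_is_invalid_with_nans(self):
        m = nematic_tensor(PlanarImage(np.full((32, 32), 3.0), 1.0), full_mask((32, 32)))
        assert not m.valid
        assert math.isnan(m.angle_deg) and math.isnan(m.anisotropy)
        assert m.n_pixels == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_isotropic_noise_has_low_anisotropy(self, seed):
        rng = np.random.default_rng(seed)
        img = PlanarImage(rng.uniform(size=(102, 102)), 1.0)
        m = nematic_tensor(img, full_mask((102, 102)))  # ~1e4 interior pixels
        assert m.anisotropy < 0.05

    @pytest.mark.parametrize("phi", [15.0, 45.0, 77.0])
    def test_rotation_equivariance(self, phi):
        base = make_texture((128, 128), 0.0, wavelength_px=10)
        rot = rotate(base.intensities, phi, order=3)  # CCW in math convention
        mask = np.zeros((128, 128), bool)
        mask[34:94, 34:94] = True  # stay clear of rotation padding
        m0 = nematic_tensor(base, mask)
        m1 = nematic_tensor(PlanarImage(rot, 1.0), mask)
        shift = (m1.angle_deg - m0.angle_deg - phi + 90) % 180 - 90
        assert abs(shift) < 1.0

    def test_intensity_scale_invariance(self):
        img = make_texture((64, 64), 40.0, noise_sd=0.1, rng=1)
        m1 = nematic_tensor(img, full_mask((64, 64)))
        scaled = PlanarImage(img.intensities * 137.0, 1.0)
        m2 = nematic_tensor(scaled, full_mask((64, 64)))
        assert m2.angle_deg == pytest.approx(m1.angle_deg, abs=1e-9)
        assert m2.anisotropy == pytest.approx(m1.anisotropy, abs=1e-9)

    def test_orthogonal_stripe_mixture_cancels(self):
        a = make_texture((64, 64), 20.0).intensities
        b = make_texture((64, 64), -70.0).intensities
        img = np.concatenate([a, b], axis=1)  # 50/50 in one mask
        m = nematic_tensor(PlanarImage(img, 1.0), full_mask((64, 128)))
        assert m.anisotropy < 0.1

    def test_anisotropy_bounded_and_angle_in_range(self, rng):
        for _ in range(5):
            img = PlanarImage(rng.uniform(size=(32, 32)), 1.0)
            m = nematic_tensor(img, rng.uniform(size=(32, 32)) > 0.3)
            if m.valid:
                assert 0.0 <= m.anisotropy <= 1.0
                assert -90.0 < m.angle_deg <= 90.0


def _roi_set(masks: dict, dims=(64, 64)):
    return CellROISet(
        ablation_id=999,
        ablation_mask=np.zeros(dims, bool),
        cell_masks=masks,
        trimmed_masks=masks,
        trim_distance_um=30.0,
        pixel_size_um=1.0,
    )


class TestQuantifyRois:
    def test_empty_mask_yields_single_invalid_entry(self):
        img = make_texture((64, 64), 10.0)
        masks = {i: np.zeros((64, 64), bool) for i in range(1, 6)}
        for i in range(1, 5):
            masks[i][10 * i : 10 * i + 8, 5:60] = True
        measures = quantify_rois(img, _roi_set(masks))
        assert len(measures) == 5
        assert sum(not m.valid for m in measures) == 1
        assert [m.cell_id for m in measures] == [1, 2, 3, 4, 5]

    def test_order_independence(self):
        img = make_texture((64, 64), 25.0, noise_sd=0.05, rng=3)
        masks = {}
        for i in range(1, 4):
            m = np.zeros((64, 64), bool)
            m[15 * i : 15 * i + 10, 4:60] = True
            masks[i] = m
        fwd = quantify_rois(img, _roi_set(masks))
        rev = quantify_rois(img, _roi_set(dict(reversed(list(masks.items())))))
        assert [(m.cell_id, m.angle_deg, m.anisotropy) for m in fwd] == [
            (m.cell_id, m.angle_deg, m.anisotropy) for m in rev
        ]

    def test_dimension_mismatch_rejected(self):
        img = make_texture((64, 64), 0.0)
        with pytest.raises(ValueError, match="dimensions"):
            quantify_rois(img, _roi_set({1: np.ones((32, 32), bool)}, dims=(32, 32)))


class TestRenderQuantification:
    def test_no_valid_measures_leaves_plain_image(self):
        img = make_texture((32, 32), 0.0)
        over = render_quantification(img, [])
        assert over.kind == "overlay"
        # all three channels equal -> pure grayscale, nothing drawn
        rgb = over.intensities
        assert (rgb[..., 0] == rgb[..., 1]).all() and (rgb[..., 1] == rgb[..., 2]).all()

    def test_zero_anisotropy_draws_a_dot(self):
        from cmtkit.orientation_quantify import OrientationMeasure

        img = PlanarImage(np.zeros((32, 32)), 1.0)
        m = OrientationMeasure(0.0, 0.0, 10, cell_id=1, centroid_yx=(16.0, 16.0))
        over = render_quantification(img, [m], color=(255, 0, 0))
        drawn = np.argwhere((over.intensities == [255, 0, 0]).all(axis=-1))
        assert len(drawn) == 1
        np.testing.assert_array_equal(drawn[0], [16, 16])

    def test_segment_endpoints_match_analytic_geometry(self):
        from cmtkit.orientation_quantify import OrientationMeasure

        img = PlanarImage(np.zeros((64, 64)), 1.0)
        horizontal = OrientationMeasure(0.0, 1.0, 10, cell_id=1, centroid_yx=(20.0, 32.0))
        vertical = OrientationMeasure(90.0, 1.0, 10, cell_id=2, centroid_yx=(44.0, 32.0))
        over = render_quantification(img, [horizontal, vertical], color=(255, 0, 0),
                                     length_scale_px=20.0)
        drawn = (over.intensities == [255, 0, 0]).all(axis=-1)
        # horizontal: y=20, x in [22, 42]; vertical: x=32, y in [34, 54]
        assert drawn[20, 22] and drawn[20, 42]
        assert drawn[34, 32] and drawn[54, 32]
        ys, xs = np.nonzero(drawn)
        assert set(ys[xs != 32]) == {20}
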