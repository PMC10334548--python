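import numpy as np
import pytest
from scipy import ndimage

from cmtkit.segmentation_roi import (
    LabelImage,
    adjacent_cells,
    build_roi_set,
    erode_rois,
    merge_labels,
    segment_cells,
    select_ablation,
    trim_by_distance,
)
from cmtkit.stack_io import PlanarImage

from conftest import grid_contour_image, grid_label_image


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_adjacent(labels: np.ndarray, ablation_id: int, max_gap: int) -> set[int]:
    """O(n^2) Chebyshev pixel-pair adjacency check."""
    ab = np.argwhere(labels == ablation_id)
    out = set()
    for lid in np.unique(labels):
        if lid in (0, ablation_id):
            continue
        pix = np.argwhere(labels == lid)
        d = np.abs(pix[:, None, :] - ab[None, :, :]).max(axis=2)
        if (d <= max_gap).any():
            out.add(int(lid))
    return out


def brute_erode_once(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion by a diamond: keep pixels whose L1-ball stays inside the mask."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            ok = True
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if abs(dy) + abs(dx) > radius:
                        continue
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                        ok = False
                        break
                if not ok:
                    break
            out[y, x] = ok
    return out


# ---------------------------------------------------------------------------


class TestSegmentCells:
    def test_grid_of_cells_segmented_with_expected_areas(self):
        # 30-px cell pitch: 28-px interiors behind 2-px bright walls, with a
        # dark margin so the surround becomes a background-frame label
        contour = grid_contour_image(3, 3, cell_px=28, wall_px=2, margin_px=6)
        result = segment_cells(contour, smooth_sigma_px=1.0, h_min=0.2)
        assert len(result.ids()) == 10  # 9 cells + background frame
        pitch, off = 30, 6 + 2 + 14  # margin + wall + half interior
        cell_ids = {int(result.labels[off + i * pitch, off + j * pitch])
                    for i in range(3) for j in range(3)}
        assert len(cell_ids) == 9 and 0 not in cell_ids
        areas = np.bincount(result.labels.ravel())
        for cid in cell_ids:
            assert areas[cid] == pytest.approx(28 * 28, rel=0.1)

    def test_watershed_lines_are_single_pixel(self):
        contour = grid_contour_image(2, 2, cell_px=20, wall_px=2)
        labels = segment_cells(contour, 1.0, 0.2).labels
        # interior boundary between any two adjacent cells is a thin 0-line:
        # no 3x3 window is entirely 0 strictly between two labels
        zero = labels == 0
        interior_zero = zero[5:-5, 5:-5]
        win = np.ones((3, 3), bool)
        assert not ndimage.binary_erosion(interior_zero, win).any()

    def test_constant_image_raises_zero_markers(self):
        flat = PlanarImage(np.ones((32, 32)), 1.0, kind="contour")
        with pytest.raises(ValueError, match="zero watershed markers"):
            segment_cells(flat, 1.0, 0.5)

    def test_marker_override_controls_label_count(self):
        contour = grid_contour_image(2, 2, cell_px=20, wall_px=2)
        markers = np.zeros(contour.intensities.shape, dtype=np.uint8)
        for y, x in [(10, 10), (10, 32), (32, 10), (32, 32)]:
            markers[y, x] = 1
        result = segment_cells(contour, 1.0, 0.2, markers=markers)
        assert len(result.ids()) == 4

    def test_determinism(self):
        contour = grid_contour_image(3, 3, noise_sd=0.05, seed=7)
        a = segment_cells(contour, 2.0, 0.2).labels
        b = segment_cells(contour, 2.0, 0.2).labels
        np.testing.assert_array_equal(a, b)


class TestSelectAblation:
    def test_point_lookup(self):
        labels = grid_label_image()
        _, lid = select_ablation(labels, point_xy=(46, 46))  # center cell
        assert lid == 5

    def test_point_on_boundary_rejected(self):
        labels = grid_label_image()
        with pytest.raises(ValueError, match="boundary"):
            select_ablation(labels, point_xy=(0, 0))

    def test_unknown_id_rejected(self):
        labels = grid_label_image()
        with pytest.raises(ValueError, match="unknown"):
            select_ablation(labels, label_id=99)

    def test_mock_group_merges_to_union(self):
        labels = grid_label_image()
        ids = [4, 5, 8, 9] if 9 in labels.ids() else [1, 2, 4, 5]
        merged, mid = select_ablation(labels, mock_ids=[4, 5, 7, 8])
        union = np.isin(labels.labels, [4, 5, 7, 8])
        merged_mask = merged.labels == mid
        # contains the union, and any extra pixels were watershed lines only
        assert (union <= merged_mask).all()
        extra = merged_mask & ~union
        assert (labels.labels[extra] == 0).all()
        # no foreign label was swallowed
        for other in (1, 2, 3, 6, 9):
            np.testing.assert_array_equal(merged.labels == other, labels.labels == other)

    def test_exactly_one_selector_required(self):
        labels = grid_label_image()
        with pytest.raises(ValueError, match="exactly one"):
            select_ablation(labels, point_xy=(46, 46), label_id=5)


class TestAdjacentCells:
    def test_plus_arrangement_four_neighbours(self):
        # center ablation with 4 edge-sharing cells, 1-px separating lines
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[12:20, 12:20] = 5  # ablation
        labels[2:11, 12:20] = 1
        labels[21:30, 12:20] = 2
        labels[12:20, 2:11] = 3
        labels[12:20, 21:30] = 4
        li = LabelImage(labels, 1.0)
        got = adjacent_cells(li, 5, max_gap_px=2)
        assert got == {1, 2, 3, 4}
        assert got == brute_adjacent(labels, 5, 2)

    def test_grid_center_has_eight_neighbours(self):
        labels = grid_label_image(3, 3)
        got = adjacent_cells(labels, 5, max_gap_px=2)
        assert got == {1, 2, 3, 4, 6, 7, 8, 9}
        assert got == brute_adjacent(labels.labels, 5, 2)

    @pytest.mark.parametrize("gap", [1, 2, 3])
    def test_matches_brute_force_on_noisy_segmentation(self, gap):
        contour = grid_contour_image(3, 3, noise_sd=0.05, seed=1)
        li = segment_cells(contour, 2.0, 0.2)
        _, center = select_ablation(li, point_xy=(48, 48))
        got = adjacent_cells(li, center, max_gap_px=gap)
        assert got == brute_adjacent(li.labels, center, gap)

    def test_isolated_ablation_returns_empty_set(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[8:12, 8:12] = 1
        assert adjacent_cells(LabelImage(labels, 1.0), 1) == set()


class TestErodeRois:
    def test_square_erosion_oracle(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[4:16, 4:16] = 1  # 12x12 square
        masks, gone = erode_rois(LabelImage(labels, 1.0), [1], iterations=3, radius_px=1)
        assert gone == []
        expected = np.zeros((20, 20), bool)
        expected[7:13, 7:13] = True  # 6x6 core
        np.testing.assert_array_equal(masks[1], expected)

    def test_small_square_erodes_to_empty_and_is_flagged(self):
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[4:9, 4:9] = 1  # 5x5
        masks, gone = erode_rois(LabelImage(labels, 1.0), [1], iterations=3)
        assert masks == {}
        assert gone == [1]

    def test_zero_iterations_is_identity(self):
        labels = grid_label_image(2, 2, cell_px=10)
        masks, _ = erode_rois(labels, [1, 2], iterations=0)
        np.testing.assert_array_equal(masks[1], labels.labels == 1)

    def test_matches_repeated_single_step_oracle(self, rng):
        blob = ndimage.binary_dilation(rng.uniform(size=(24, 24)) > 0.9, iterations=3)
        labels = LabelImage(ndimage.label(blob)[0].astype(np.int32), 1.0)
        target = labels.ids()[0]
        masks, gone = erode_rois(labels, [target], iterations=2, radius_px=1)
        oracle = labels.labels == target
        for _ in range(2):
            oracle = brute_erode_once(oracle, 1)
        if target in masks:
            np.testing.assert_array_equal(masks[target], oracle)
        else:
            assert not oracle.any()


class TestTrimByDistance:
    def test_rectangle_trim_matches_distance_oracle(self):
        # straight ablation edge along x; cell spans 10..50 um away
        h, w = 80, 40
        ablation = np.zeros((h, w), bool)
        ablation[:5] = True
        cell = np.zeros((h, w), bool)
        cell[15:55] = True  # 10..50 um at 1 um/px from ablation edge at y=4
        trimmed, _ = trim_by_distance({1: cell}, ablation, 30.0, 1.0)
        dist = ndimage.distance_transform_edt(~ablation)
        expected = cell & (dist <= 30.0)
        np.testing.assert_array_equal(trimmed[1], expected)
        assert trimmed[1].sum() == expected.sum() > 0

    def test_infinite_distance_is_no_trim(self):
        ablation = np.zeros((20, 20), bool)
        ablation[0, 0] = True
        cell = np.zeros((20, 20), bool)
        cell[10:15, 10:15] = True
        trimmed, _ = trim_by_distance({1: cell}, ablation, np.inf, 1.0)
        np.testing.assert_array_equal(trimmed[1], cell)

    def test_cell_beyond_reach_excluded(self):
        ablation = np.zeros((60, 60), bool)
        ablation[0:2, 0:2] = True
        cell = np.zeros((60, 60), bool)
        cell[50:58, 50:58] = True
        trimmed, emptied = trim_by_distance({7: cell}, ablation, 30.0, 1.0)
        assert 7 not in trimmed
        assert emptied == [7]


class TestBuildRoiSet:
    def test_nesting_invariant_holds_for_every_cell(self):
        contour = grid_contour_image(3, 3, cell_px=30, wall_px=2, noise_sd=0.03, seed=5)
        li = segment_cells(contour, 2.0, 0.2)
        _, center = select_ablation(li, point_xy=(48, 48))
        roi_set = build_roi_set(li, center, trim_distance_um=25.0)
        assert roi_set.cell_masks, "expected at least one analysed cell"
        for cid, eroded in roi_set.cell_masks.items():
            region = li.labels == cid
            trimmed = roi_set.trimmed_masks[cid]
            assert (trimmed <= eroded).all()
            assert (eroded <= region).all()

    def test_excluded_cells_are_dropped(self):
        labels = grid_label_image(3, 3)
        roi_set = build_roi_set(labels, 5, trim_distance_um=100.0, excluded_cells=[1, 9])
        assert 1 not in roi_set.cell_masks and 9 not in roi_set.cell_masks
        assert {1, 9} <= set(roi_set.excluded_ids)
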