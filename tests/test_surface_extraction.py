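import numpy as np
import pytest
from scipy import ndimage

from cmtkit.stack_io import VoxelGrid
from cmtkit.surface_extraction import (
    binarize_volume,
    column_fill_surface,
    extract_shell_projection,
    surfcut,
)
from cmtkit.synthetic_data import embed_surface_volume, make_texture

VOX = (0.5, 0.31, 0.31)


class TestBinarize:
    def test_step_threshold_without_blur(self):
        vol = np.zeros((4, 6, 6))
        vol[2, 1:4, 1:4] = 100.0
        mask = binarize_volume(VoxelGrid(vol, VOX), 0.0, 50.0)
        np.testing.assert_array_equal(mask.intensities, vol == 100.0)

    def test_degenerate_threshold_warns_all_true(self):
        vol = np.full((3, 4, 4), 10.0)
        with pytest.warns(UserWarning, match="all-true"):
            mask = binarize_volume(VoxelGrid(vol, VOX), 0.0, 0.0)
        assert mask.intensities.all()

    def test_blur_reduces_component_count(self, rng):
        # noisy shell: blurring merges speckle into fewer connected components
        vol = np.zeros((8, 40, 40))
        vol[3] = 1.0
        vol += rng.uniform(size=vol.shape) * 0.9
        grid = VoxelGrid(vol, VOX)
        n_sharp = ndimage.label(binarize_volume(grid, 0.0, 0.8).intensities)[1]
        n_blurred = ndimage.label(binarize_volume(grid, 2.0, 0.5).intensities)[1]
        assert n_blurred < n_sharp


class TestSurfaceDetection:
    def test_tilted_plane_recovered_exactly(self):
        nz, ny, nx = 6, 4, 16
        vol = np.zeros((nz, ny, nx), dtype=bool)
        zs = np.arange(nz)[:, None, None]
        plane = (np.arange(nx) // 4)[None, None, :]
        vol |= zs >= plane  # filled below the tilted surface
        dm = column_fill_surface(VoxelGrid(vol, VOX))
        assert not dm.no_surface.any()
        np.testing.assert_array_equal(dm.depth, np.broadcast_to(plane[0], (ny, nx)))

    def test_all_false_marks_no_surface(self):
        dm = column_fill_surface(VoxelGrid(np.zeros((3, 4, 4), bool), VOX))
        assert dm.no_surface.all()

    def test_all_true_gives_zero_depth(self):
        dm = column_fill_surface(VoxelGrid(np.ones((3, 4, 4), bool), VOX))
        assert not dm.no_surface.any()
        assert (dm.depth == 0).all()


class TestShellProjection:
    def test_bright_voxel_inside_shell_is_projected(self, rng):
        # flat surface at z=3; one bright voxel per column at z=5; shell [5, 6)
        nz, ny, nx = 8, 5, 5
        vol = rng.uniform(0.0, 0.1, size=(nz, ny, nx))
        bright = rng.uniform(1.0, 2.0, size=(ny, nx))
        vol[5] = bright
        surface = np.zeros((nz, ny, nx), bool)
        surface[3:] = True
        dm = column_fill_surface(VoxelGrid(surface, VOX))
        proj = extract_shell_projection(VoxelGrid(vol, VOX), dm, 2, 3, "max")
        np.testing.assert_allclose(proj.intensities, bright)
        assert proj.pixel_size_um == VOX[2]

    def test_full_depth_shell_equals_zmax(self, rng):
        vol = rng.uniform(size=(6, 7, 7))
        dm = column_fill_surface(VoxelGrid(np.ones_like(vol, dtype=bool), VOX))
        proj = extract_shell_projection(VoxelGrid(vol, VOX), dm, 0, 6, "max")
        np.testing.assert_allclose(proj.intensities, vol.max(axis=0))

    def test_no_surface_column_projects_zero(self, rng):
        vol = rng.uniform(0.5, 1.0, size=(4, 3, 3))
        surface = np.ones((4, 3, 3), bool)
        surface[:, 1, 1] = False
        dm = column_fill_surface(VoxelGrid(surface, VOX))
        proj = extract_shell_projection(VoxelGrid(vol, VOX), dm, 0, 2, "max")
        assert proj.intensities[1, 1] == 0.0
        assert (proj.intensities > 0).sum() == 8

    def test_disjoint_shells_combine_under_max(self, rng):
        vol = rng.uniform(size=(10, 6, 6))
        surface = np.ones_like(vol, dtype=bool)
        dm = column_fill_surface(VoxelGrid(surface, VOX))
        grid = VoxelGrid(vol, VOX)
        pa = extract_shell_projection(grid, dm, 0, 4, "max").intensities
        pb = extract_shell_projection(grid, dm, 4, 9, "max").intensities
        pab = extract_shell_projection(grid, dm, 0, 9, "max").intensities
        np.testing.assert_allclose(np.maximum(pa, pb), pab)

    def test_invariant_to_intensity_outside_shell(self, rng):
        nz, ny, nx = 10, 6, 6
        vol = rng.uniform(size=(nz, ny, nx))
        surface = np.ones((nz, ny, nx), bool)
        dm = column_fill_surface(VoxelGrid(surface, VOX))
        proj1 = extract_shell_projection(VoxelGrid(vol, VOX), dm, 2, 5, "max").intensities
        scrambled = vol.copy()
        outside = np.ones((nz, ny, nx), bool)
        outside[2:5] = False
        scrambled[outside] = rng.uniform(size=int(outside.sum()))
        proj2 = extract_shell_projection(VoxelGrid(scrambled, VOX), dm, 2, 5, "max").intensities
        np.testing.assert_allclose(proj1, proj2)


class TestEmbeddedVolumeRecovery:
    """Cross-module round trips against the synthetic surface volume."""

    def test_flat_profile_depth_recovered_exactly(self):
        cmt = make_texture((24, 24), 30.0)
        contour = make_texture((24, 24), 0.0)
        grid = embed_surface_volume(cmt, contour, "flat", depth0=3)
        dm = column_fill_surface(binarize_volume(grid, 0.0, 0.1))
        assert (dm.depth == 3).all()

    def test_dome_profile_depth_recovered_exactly(self):
        cmt = make_texture((40, 40), 30.0)
        contour = make_texture((40, 40), 0.0)
        grid = embed_surface_volume(cmt, contour, "dome", nz=24, depth0=2, dome_amplitude=10)
        dm = column_fill_surface(binarize_volume(grid, 0.0, 0.1))
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        r2 = ((yy - 20) / 20) ** 2 + ((xx - 20) / 20) ** 2
        expected = 2 + np.round(10 * r2 / 2.0).astype(int)
        np.testing.assert_array_equal(dm.depth, expected)

    def test_profile_exceeding_stack_depth_rejected(self):
        cmt = make_texture((8, 8), 0.0)
        with pytest.raises(ValueError, match="exceeds"):
            embed_surface_volume(cmt, cmt, "flat", nz=10, depth0=5, d2=10)

    def test_shell_projections_recover_embedded_textures(self):
        cmt = make_texture((48, 48), 60.0, wavelength_px=8)
        contour = make_texture((48, 48), -30.0, wavelength_px=12)
        grid = embed_surface_volume(cmt, contour, "dome", nz=24, depth0=2,
                                    dome_amplitude=8, d1=4, d2=10)
        from cmtkit.surface_extraction import ShellParams

        cmt_img, con_img = surfcut(
            grid,
            cmt=ShellParams(0.0, 0.1, 0, 4),
            contour=ShellParams(0.0, 0.1, 4, 10),
        )
        for recovered, truth in ((cmt_img, cmt), (con_img, contour)):
            r = np.corrcoef(recovered.intensities.ravel(), truth.intensities.ravel())[0, 1]
            assert r > 0.95
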