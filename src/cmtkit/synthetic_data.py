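"""Synthetic tissue fixtures with exact ground truth.

Generates the study conditions in miniature: a grid of epidermal cells
separated by bright contour walls, a dark ablation region (a block of
destroyed cells, as in the manual-needle protocol), and a stripe-textured
cortical-microtubule signal per cell whose orientation relaxes exponentially
from its initial offset toward the local circumferential direction:

    angle_to_circumferential(t) = a0 * exp(-t / tau)

with ``tau = inf`` freezing the dynamics (the mock condition keeps uniform
random frozen orientations and designates a group of intact cells as a
pseudo-ablation).  Alignment quality is programmed as a linear ramp of the
stripe weight against an isotropic noise floor, emulating the anisotropy rise
seen after ablation.

The circumferential ground truth at a cell is the tangent of the ablation's
Euclidean-distance-transform level line at the cell centroid — the same
geometry the stress-proxy module draws — so cross-module tests are
self-consistent.  Default calibration mirrors a typical confocal acquisition:
0.31 um/px, 13 timepoints at 20-min intervals.

All generators are deterministic given the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack_io import PlanarImage, Timelapse, VoxelGrid

__all__ = [
    "SyntheticScenario",
    "make_texture",
    "make_ablation_mask",
    "make_tissue_timelapse",
    "embed_surface_volume",
    "match_cells_to_truth",
    "TRUTH_COLUMNS",
]

#: Ground-truth table schema; join-compatible with AngleRecord on
#: (cell_id, timepoint_min).
TRUTH_COLUMNS = (
    "cell_id",
    "timepoint_min",
    "true_angle_deg",
    "true_circ_angle_deg",
    "true_angle_to_circ_deg",
    "programmed_anisotropy",
    "centroid_y",
    "centroid_x",
)


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic timelapse experiment.

    The defaults are the reference conditions used throughout the test
    suite: a 5x5 grid of 97-px (about 30 um) cells, a 2x2-cell ablation
    block, initial angle offset a0 = 45 deg relaxing with tau = 80 min over
    13 timepoints at 20-min intervals, stripes of 8-px wavelength.
    """

    grid_rows: int = 5
    grid_cols: int = 5
    cell_size_px: int = 97
    wall_width_px: int = 2
    pixel_size_um: float = 0.31
    #: inclusive (row, col) index ranges of the ablated cell block
    ablation_block: tuple[tuple[int, int], tuple[int, int]] = ((1, 2), (1, 2))
    condition: str = "ablation"  # "ablation" darkens the block; "mock" keeps it intact
    #: initial angle-to-circumferential magnitude (deg) for angle_dist="offset"
    a0_deg: float = 45.0
    #: per-cell initial angle distribution: "offset" (a0 with random sign
    #: about the circumferential direction) or "uniform" on (-90, 90]
    angle_dist: str = "offset"
    #: reorientation time constant in minutes; math.inf freezes the dynamics
    tau_min: float = 80.0
    n_timepoints: int = 13
    interval_min: float = 20.0
    stripe_wavelength_px: float = 8.0
    stripe_contrast: float = 1.0
    noise_sd: float = 0.1
    #: programmed alignment level (stripe weight vs isotropic floor),
    #: ramping linearly over the timelapse
    anisotropy_start: float = 0.5
    anisotropy_end: float = 0.9
    wall_intensity_cmt: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_min < 0:
            raise ValueError("tau_min must be >= 0 (or inf)")
        if self.condition not in ("ablation", "mock"):
            raise ValueError("condition must be 'ablation' or 'mock'")
        if self.angle_dist not in ("offset", "uniform"):
            raise ValueError("angle_dist must be 'offset' or 'uniform'")
        if min(self.grid_rows, self.grid_cols, self.cell_size_px, self.wall_width_px) < 1:
            raise ValueError("grid and cell dimensions must be positive")
        (r0, r1), (c0, c1) = self.ablation_block
        if not (0 <= r0 <= r1 < self.grid_rows and 0 <= c0 <= c1 < self.grid_cols):
            raise ValueError("ablation block must lie inside the cell grid")

    @property
    def canvas_shape(self) -> tuple[int, int]:
        pitch = self.cell_size_px + self.wall_width_px
        return (
            self.grid_rows * pitch + self.wall_width_px,
            self.grid_cols * pitch + self.wall_width_px,
        )

    def timepoints(self) -> np.ndarray:
        return np.arange(self.n_timepoints, dtype=np.float64) * self.interval_min

    def cell_slices(self, i: int, j: int) -> tuple[slice, slice]:
        """Interior (rows, cols) of grid cell (i, j), walls excluded."""
        pitch = self.cell_size_px + self.wall_width_px
        r0 = i * pitch + self.wall_width_px
        c0 = j * pitch + self.wall_width_px
        return slice(r0, r0 + self.cell_size_px), slice(c0, c0 + self.cell_size_px)

    def ablation_mask(self) -> np.ndarray:
        """Mask of the ablated (or mock-designated) block, internal walls included."""
        (r0, r1), (c0, c1) = self.ablation_block
        top = self.cell_slices(r0, c0)
        bot = self.cell_slices(r1, c1)
        mask = np.zeros(self.canvas_shape, dtype=bool)
        mask[top[0].start : bot[0].stop, top[1].start : bot[1].stop] = True
        return mask

    def tissue_cells(self) -> list[tuple[int, int]]:
        """Grid indices of intact cells (everything outside the ablation block)."""
        (r0, r1), (c0, c1) = self.ablation_block
        return [
            (i, j)
            for i in range(self.grid_rows)
            for j in range(self.grid_cols)
            if not (r0 <= i <= r1 and c0 <= j <= c1)
        ]


def make_texture(
    dims: tuple[int, int],
    angle_deg: float,
    wavelength_px: float = 8.0,
    contrast: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> PlanarImage:
    """Sinusoidal stripe field at a given (mathematical-convention) orientation.

    Stripes run along ``angle_deg`` (CCW from +x, y up); intensity is
    ``contrast * [0, 1]`` plus seeded Gaussian noise.  At 0 deg, rows are
    constant along x and columns are periodic with the set wavelength.
    """
    if wavelength_px < 4:
        raise ValueError("wavelength_px must be >= 4 for a resolvable stripe field")
    h, w = dims
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    th = math.radians(angle_deg)
    # phase along the stripe normal; image y points down, so Y_math = -y
    s = -xx * math.sin(th) - yy * math.cos(th)
    img = contrast * 0.5 * (1.0 + np.sin(2.0 * math.pi * s / wavelength_px))
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        img = img + gen.normal(0.0, noise_sd, size=img.shape)
    return PlanarImage(np.clip(img, 0.0, None), pixel_size_um=1.0, kind="projection")


def make_ablation_mask(
    dims: tuple[int, int],
    shape: str = "disk",
    center: tuple[float, float] | None = None,
    radii: tuple[float, float] | float = 10.0,
    notch_angle_deg: float = 90.0,
) -> np.ndarray:
    """Parametric ablation shapes for geometry tests: disk, ellipse, C-shape.

    The C-shape is a disk with an angular notch (opening toward +x) removed,
    leaving a concave region for convex-hull tests.
    """
    h, w = dims
    cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    ry, rx = (radii, radii) if np.isscalar(radii) else radii
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    if shape == "disk" or shape == "ellipse":
        return inside
    if shape == "c-shape":
        ang = np.degrees(np.arctan2(-(yy - cy), xx - cx))  # math convention
        notch = np.abs(ang) <= notch_angle_deg / 2.0
        return inside & ~notch
    raise ValueError(f"unknown ablation shape {shape!r}")


def _circumferential_angle(dist: np.ndarray, cy: float, cx: float) -> float:
    """Tangent orientation (deg, math convention) of the distance level line
    at (cy, cx), from the smoothed distance-transform gradient."""
    smooth = ndimage.gaussian_filter(dist, sigma=2.0)
    r, c = int(round(cy)), int(round(cx))
    gy = (smooth[r + 1, c] - smooth[r - 1, c]) / 2.0
    gx = (smooth[r, c + 1] - smooth[r, c - 1]) / 2.0
    # gradient points radially outward (image coords); tangent is its 90-deg
    # rotation, converted to math convention by flipping y
    ang = math.degrees(math.atan2(gx, gy))  # atan2(-(-gy), gx) rotated
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return ang


def make_tissue_timelapse(
    scenario: SyntheticScenario,
) -> tuple[Timelapse, Timelapse, pd.DataFrame]:
    """Render the synthetic timelapse.

    Returns ``(cmt_series, contour_series, ground_truth)``: per timepoint a
    stripe-textured CMT image and a bright-walled contour image, plus the
    exact per-(cell, timepoint) ground-truth table (:data:`TRUTH_COLUMNS`).
    Cell ids number the intact cells in row-major grid order starting at 1.
    """
    sc = scenario
    h, w = sc.canvas_shape
    rng = np.random.default_rng(sc.seed)
    ablation = sc.ablation_mask()
    dist = ndimage.distance_transform_edt(~ablation)
    cells = sc.tissue_cells()
    times = sc.timepoints()

    # per-cell static draws
    circ: dict[int, float] = {}
    init_offset: dict[int, float] = {}
    centroids: dict[int, tuple[float, float]] = {}
    for cid, (i, j) in enumerate(cells, start=1):
        rs, cs = sc.cell_slices(i, j)
        cy = (rs.start + rs.stop - 1) / 2.0
        cx = (cs.start + cs.stop - 1) / 2.0
        centroids[cid] = (cy, cx)
        circ[cid] = _circumferential_angle(dist, cy, cx)
        if sc.angle_dist == "uniform":
            init_offset[cid] = float(rng.uniform(-90.0, 90.0))
        else:
            init_offset[cid] = float(rng.choice([-1.0, 1.0]) * sc.a0_deg)

    # static contour geometry: walls bright, interiors dark
    contour_base = np.ones((h, w), dtype=np.float64)
    for i in range(sc.grid_rows):
        for j in range(sc.grid_cols):
            rs, cs = sc.cell_slices(i, j)
            contour_base[rs, cs] = 0.05
    if sc.condition == "ablation":
        inner = ndimage.binary_erosion(ablation, iterations=sc.wall_width_px)
        contour_base[inner] = 0.0  # wound is dark but keeps its bounding wall

    cmt_frames: list[PlanarImage] = []
    contour_frames: list[PlanarImage] = []
    truth_rows: list[dict] = []
    ramp = np.linspace(sc.anisotropy_start, sc.anisotropy_end, sc.n_timepoints)

    for ti, t in enumerate(times):
        # exp(-t/tau) in the tau->0 limit: 1 at t=0, 0 afterwards
        if sc.tau_min == 0:
            decay = 1.0 if t == 0 else 0.0
        elif math.isfinite(sc.tau_min):
            decay = math.exp(-t / sc.tau_min)
        else:
            decay = 1.0
        weight = float(ramp[ti])
        cmt = np.zeros((h, w), dtype=np.float64)
        cmt += sc.wall_intensity_cmt * (contour_base > 0.5)
        for cid, (i, j) in enumerate(cells, start=1):
            rs, cs = sc.cell_slices(i, j)
            if sc.angle_dist == "uniform":
                angle = init_offset[cid] if not math.isfinite(sc.tau_min) else (
                    circ[cid] + (init_offset[cid] - circ[cid]) * decay
                )
                a2c = _acute(angle - circ[cid])
            else:
                offset = init_offset[cid] * decay
                angle = _wrap_axial(circ[cid] + offset)
                a2c = abs(offset)
            tex = make_texture(
                (rs.stop - rs.start, cs.stop - cs.start),
                angle_deg=angle,
                wavelength_px=sc.stripe_wavelength_px,
                contrast=sc.stripe_contrast,
            ).intensities
            floor = 0.5 * sc.stripe_contrast
            cmt[rs, cs] = weight * tex + (1.0 - weight) * floor
            truth_rows.append(
                {
                    "cell_id": cid,
                    "timepoint_min": float(t),
                    "true_angle_deg": _wrap_axial(angle),
                    "true_circ_angle_deg": circ[cid],
                    "true_angle_to_circ_deg": a2c,
                    "programmed_anisotropy": weight,
                    "centroid_y": centroids[cid][0],
                    "centroid_x": centroids[cid][1],
                }
            )
        if sc.condition == "ablation":
            cmt[ablation] = 0.0
        if sc.noise_sd > 0:
            cmt = cmt + rng.normal(0.0, sc.noise_sd, size=cmt.shape)
            contour = contour_base + rng.normal(0.0, sc.noise_sd, size=contour_base.shape)
        else:
            contour = contour_base.copy()
        cmt_frames.append(
            PlanarImage(np.clip(cmt, 0.0, None), sc.pixel_size_um, kind="projection", timepoint_min=t)
        )
        contour_frames.append(
            PlanarImage(np.clip(contour, 0.0, None), sc.pixel_size_um, kind="contour", timepoint_min=t)
        )

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return (
        Timelapse(cmt_frames, interval_min=sc.interval_min),
        Timelapse(contour_frames, interval_min=sc.interval_min),
        truth,
    )


def _wrap_axial(angle_deg: float) -> float:
    """Wrap an axial orientation to (-90, 90]."""
    a = math.fmod(angle_deg, 180.0)
    if a <= -90.0:
        a += 180.0
    elif a > 90.0:
        a -= 180.0
    return a


def _acute(diff_deg: float) -> float:
    d = math.fmod(abs(diff_deg), 180.0)
    return min(d, 180.0 - d)


def match_cells_to_truth(roi_set, truth: pd.DataFrame) -> dict[int, int]:
    """Map pipeline cell ids (watershed labels) to ground-truth cell ids.

    A watershed label is matched to the truth cell whose recorded centroid
    falls inside (or nearest to) the label's eroded mask centroid.  Used only
    by tests and the acceptance script to compare recovered angles with
    programmed ones.
    """
    truth_cells = truth.drop_duplicates("cell_id")[["cell_id", "centroid_y", "centroid_x"]]
    mapping: dict[int, int] = {}
    for label_id, mask in roi_set.cell_masks.items():
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        d2 = (truth_cells["centroid_y"] - cy) ** 2 + (truth_cells["centroid_x"] - cx) ** 2
        mapping[label_id] = int(truth_cells.iloc[int(np.argmin(d2.to_numpy()))]["cell_id"])
    return mapping


def embed_surface_volume(
    cmt: PlanarImage,
    contour: PlanarImage,
    surface_profile: str | np.ndarray = "flat",
    nz: int = 20,
    depth0: int = 3,
    d1: int = 4,
    d2: int = 10,
    dome_amplitude: int = 8,
    base_intensity: float = 0.2,
    z_step_um: float = 0.5,
) -> VoxelGrid:
    """Embed a CMT/contour image pair into a 3D stack under a known surface.

    The first supra-threshold voxel of each column sits at the surface depth
    map (``"flat"``: constant ``depth0``; ``"dome"``: a parabolic dome of the
    given amplitude, deepest at the corners; or an explicit integer map).
    CMT signal occupies slices ``[depth, depth+d1)`` below the surface and
    contour signal ``[depth+d1, depth+d2)``; a constant ``base_intensity`` is
    added throughout the shell so surface detection is exact at any
    threshold below it.
    """
    if cmt.intensities.shape != contour.intensities.shape:
        raise ValueError("cmt and contour images must share dimensions")
    h, w = cmt.intensities.shape
    if isinstance(surface_profile, str):
        if surface_profile == "flat":
            depth = np.full((h, w), depth0, dtype=np.intp)
        elif surface_profile == "dome":
            yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
            r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
            depth = depth0 + np.round(dome_amplitude * r2 / 2.0).astype(np.intp)
        else:
            raise ValueError(f"unknown surface profile {surface_profile!r}")
    else:
        depth = np.asarray(surface_profile, dtype=np.intp)
        if depth.shape != (h, w):
            raise ValueError("explicit surface profile must match image shape")
    if int(depth.max()) + d2 > nz:
        raise ValueError("surface profile plus shell depth exceeds the stack")

    vol = np.zeros((nz, h, w), dtype=np.float64)
    zs = np.arange(nz)[:, None, None]
    in_cmt = (zs >= depth) & (zs < depth + d1)
    in_con = (zs >= depth + d1) & (zs < depth + d2)
    vol += in_cmt * (base_intensity + cmt.intensities[None, :, :])
    vol += in_con * (base_intensity + contour.intensities[None, :, :])
    return VoxelGrid(vol, (z_step_um, cmt.pixel_size_um, cmt.pixel_size_um))
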