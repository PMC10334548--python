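"""Cell segmentation and ROI construction around an ablation.

The averaged cell-contour image is watershed-segmented into labeled cells
(the ablation site is one of the labels).  The ablation label is designated
non-interactively (a point, a label id, or a merge list for mock ablations),
the single row of cells bordering it is selected through a region adjacency
criterion, each selected cell is eroded to exclude edge signal, and finally
trimmed to a fixed physical distance from the ablation so only signal exposed
to comparable stress levels is analyzed.

Determinism: the watershed and every morphological step here are
deterministic for identical inputs and parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.morphology import diamond, h_minima
from skimage.segmentation import watershed

from .stack_io import PlanarImage

__all__ = [
    "LabelImage",
    "CellROISet",
    "segment_cells",
    "select_ablation",
    "merge_labels",
    "adjacent_cells",
    "erode_rois",
    "trim_by_distance",
    "build_roi_set",
]

log = logging.getLogger(__name__)


@dataclass
class LabelImage:
    """Watershed labels: 0 on boundary/background lines, positive per region."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        self.pixel_size_um = float(self.pixel_size_um)

    def ids(self) -> list[int]:
        u = np.unique(self.labels)
        return [int(i) for i in u if i > 0]

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id


@dataclass
class CellROISet:
    """Ablation mask plus per-cell eroded and trimmed analysis masks.

    Invariant (asserted on construction): ``trimmed ⊆ eroded`` for every
    cell, masks are pairwise disjoint, and the ablation id is not a cell id.
    """

    ablation_id: int
    ablation_mask: np.ndarray
    cell_masks: dict[int, np.ndarray]
    trimmed_masks: dict[int, np.ndarray]
    trim_distance_um: float
    pixel_size_um: float
    excluded_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ablation_id in self.cell_masks:
            raise ValueError("ablation_id must not appear among cell ids")
        acc = np.zeros_like(self.ablation_mask, dtype=np.int32)
        for cid, mask in self.cell_masks.items():
            trimmed = self.trimmed_masks.get(cid)
            if trimmed is not None and np.any(trimmed & ~mask):
                raise ValueError(f"trimmed mask of cell {cid} is not a subset of its eroded mask")
            acc += mask.astype(np.int32)
        if np.any(acc > 1):
            raise ValueError("cell masks must be pairwise disjoint")


def segment_cells(
    contour: PlanarImage,
    smooth_sigma_px: float = 2.0,
    h_min: float = 0.1,
    markers: np.ndarray | None = None,
) -> LabelImage:
    """Marker-controlled watershed of a bright-walled cell-contour image.

    The contour image is Gaussian-smoothed and treated as a topographic
    surface (walls = ridges).  Markers are the regional minima that survive
    depth-``h_min`` suppression; a user marker image (non-zero seeds)
    overrides them, replacing the original workflow's interactive correction.
    Watershed ridge lines are labeled 0 and are 1 px wide.
    """
    img = np.asarray(contour.intensities, dtype=np.float64)
    smoothed = gaussian(img, sigma=smooth_sigma_px, preserve_range=True) if smooth_sigma_px > 0 else img

    if markers is not None:
        marker_labels, n_markers = ndimage.label(np.asarray(markers) > 0)
    else:
        minima = h_minima(smoothed, h_min)
        marker_labels, n_markers = ndimage.label(minima)
    if n_markers == 0:
        raise ValueError("zero watershed markers found (constant image or h_min too large)")

    labels = watershed(smoothed, markers=marker_labels, watershed_line=True)
    return LabelImage(labels.astype(np.int32), contour.pixel_size_um)


def merge_labels(labels: LabelImage, ids: set[int] | list[int], new_id: int | None = None) -> tuple[LabelImage, int]:
    """Merge a group of labels into one region (mock-ablation designation).

    The 1-px watershed lines separating the merged regions are absorbed into
    the merged region (a line pixel joins if all its positive neighbours are
    members).  Returns the new label image and the merged id.
    """
    ids = sorted(int(i) for i in ids)
    if not ids:
        raise ValueError("empty merge list")
    arr = labels.labels
    for i in ids:
        if not np.any(arr == i):
            raise ValueError(f"label {i} not present")
    new_id = int(new_id if new_id is not None else ids[0])
    out = arr.copy()
    member = np.isin(arr, ids)
    out[member] = new_id

    # absorb internal watershed lines: 0-pixels whose 8-neighbourhood contains
    # member pixels and no foreign positive label
    near_member = ndimage.binary_dilation(member, structure=np.ones((3, 3), bool))
    foreign = (arr > 0) & ~member
    near_foreign = ndimage.binary_dilation(foreign, structure=np.ones((3, 3), bool))
    absorb = (arr == 0) & near_member & ~near_foreign
    out[absorb] = new_id
    return LabelImage(out, labels.pixel_size_um), new_id


def select_ablation(
    labels: LabelImage,
    point_xy: tuple[float, float] | None = None,
    label_id: int | None = None,
    mock_ids: list[int] | None = None,
) -> tuple[LabelImage, int]:
    """Designate the ablation label non-interactively.

    Exactly one selector must be given: a point ``(x, y)`` lying on a
    positive label, an existing label id, or a list of ids merged into a
    single pseudo-ablation (the mock-experiment case, where a group of intact
    cells stands in for the wound).  Returns (possibly merged) labels and the
    ablation id.
    """
    n_given = sum(s is not None for s in (point_xy, label_id, mock_ids))
    if n_given != 1:
        raise ValueError("give exactly one of point_xy, label_id, mock_ids")
    if mock_ids is not None:
        return merge_labels(labels, mock_ids)
    if point_xy is not None:
        x, y = point_xy
        r, c = int(round(y)), int(round(x))
        if not (0 <= r < labels.labels.shape[0] and 0 <= c < labels.labels.shape[1]):
            raise ValueError(f"point {point_xy} is outside the image")
        lid = int(labels.labels[r, c])
        if lid == 0:
            raise ValueError(f"point {point_xy} lies on a watershed boundary (label 0)")
        return labels, lid
    assert label_id is not None
    if not np.any(labels.labels == label_id):
        raise ValueError(f"unknown label id {label_id}")
    return labels, int(label_id)


def adjacent_cells(labels: LabelImage, ablation_id: int, max_gap_px: int = 2) -> set[int]:
    """Ids of labels with a pixel within Chebyshev distance ``max_gap_px`` of
    the ablation — the single row of directly neighbouring cells.

    The default gap of 2 px bridges the 1-px watershed line and includes
    corner-touching labels.  The ablation itself and background 0 are never
    returned; an empty result is allowed (and logged).
    """
    arr = labels.labels
    if not np.any(arr == ablation_id):
        raise ValueError(f"ablation id {ablation_id} not present")
    footprint = np.ones((2 * max_gap_px + 1,) * 2, dtype=bool)  # Chebyshev ball
    near = ndimage.binary_dilation(arr == ablation_id, structure=footprint)
    ids = set(int(i) for i in np.unique(arr[near])) - {0, int(ablation_id)}
    if not ids:
        log.info("no cells adjacent to ablation %d within %d px", ablation_id, max_gap_px)
    return ids


def erode_rois(
    labels: LabelImage,
    ids,
    iterations: int = 3,
    radius_px: int = 1,
) -> tuple[dict[int, np.ndarray], list[int]]:
    """Erode each selected region ``iterations`` times by a radius-``radius_px``
    diamond (4-neighbourhood) element, excluding cell-edge signal.

    Regions eroded away completely are excluded and reported in the second
    return value.
    """
    selem = diamond(radius_px)
    masks: dict[int, np.ndarray] = {}
    vanished: list[int] = []
    for cid in sorted(int(i) for i in ids):
        mask = labels.labels == cid
        if not mask.any():
            raise ValueError(f"label {cid} not present")
        for _ in range(iterations):
            mask = ndimage.binary_erosion(mask, structure=selem)
        if mask.any():
            masks[cid] = mask
        else:
            vanished.append(cid)
            log.info("cell %d eroded to empty; excluded", cid)
    return masks, vanished


def trim_by_distance(
    rois: dict[int, np.ndarray],
    ablation_mask: np.ndarray,
    max_dist_um: float,
    pixel_size_um: float,
) -> tuple[dict[int, np.ndarray], list[int]]:
    """Keep only ROI pixels within ``max_dist_um`` of the nearest ablation pixel.

    Uses the exact Euclidean distance transform.  Cells trimmed to empty are
    excluded and reported.
    """
    if max_dist_um <= 0:
        raise ValueError("max_dist_um must be positive")
    dist_px = ndimage.distance_transform_edt(~np.asarray(ablation_mask, dtype=bool))
    keep = dist_px <= max_dist_um / pixel_size_um
    trimmed: dict[int, np.ndarray] = {}
    emptied: list[int] = []
    for cid, mask in rois.items():
        t = mask & keep
        if t.any():
            trimmed[cid] = t
        else:
            emptied.append(cid)
            log.info("cell %d lies entirely beyond %.1f um; excluded", cid, max_dist_um)
    return trimmed, emptied


def build_roi_set(
    labels: LabelImage,
    ablation_id: int,
    trim_distance_um: float,
    max_gap_px: int = 2,
    erode_iterations: int = 3,
    erode_radius_px: int = 1,
    excluded_cells: list[int] | None = None,
) -> CellROISet:
    """Full ROI construction: adjacency -> manual exclusions -> erosion -> trim."""
    neighbours = adjacent_cells(labels, ablation_id, max_gap_px=max_gap_px)
    excluded = list(excluded_cells or [])
    analysed = sorted(neighbours - set(excluded))
    eroded, vanished = erode_rois(labels, analysed, iterations=erode_iterations, radius_px=erode_radius_px)
    ablation_mask = labels.labels == ablation_id
    trimmed, emptied = trim_by_distance(eroded, ablation_mask, trim_distance_um, labels.pixel_size_um)
    # cells whose trim emptied them drop out of the analysed set entirely
    eroded = {cid: m for cid, m in eroded.items() if cid in trimmed}
    return CellROISet(
        ablation_id=int(ablation_id),
        ablation_mask=ablation_mask,
        cell_masks=eroded,
        trimmed_masks=trimmed,
        trim_distance_um=float(trim_distance_um),
        pixel_size_um=labels.pixel_size_um,
        excluded_ids=sorted(set(excluded) | set(vanished) | set(emptied)),
    )
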