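"""Timelapse registration and contour averaging.

The cell-contour signal of a single frame is often too weak or variable near
the ablation for reliable segmentation.  Because the sample moves little
between timepoints, registering every frame to the first with an affine
transform and averaging the aligned series strongly sharpens the contour
signal, and the single averaged image then defines one segmentation (hence
stable cell ids) for the whole timelapse.

Transforms are estimated from SIFT keypoint matches with RANSAC consensus
outlier rejection.  If fewer than ``MIN_INLIERS`` matches survive, or the
estimated transform does not improve image similarity, the frame falls back
to the identity transform and is flagged — registration failure never aborts
the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform, warp

from .stack_io import PlanarImage, Timelapse

__all__ = ["AffineTransform2D", "estimate_affine", "align_series", "average_projection", "MIN_INLIERS"]

log = logging.getLogger(__name__)

#: Minimum RANSAC inlier count below which registration degrades to identity.
MIN_INLIERS = 6


@dataclass
class AffineTransform2D:
    """A 2D affine map from the moving image's frame into the fixed frame.

    Coordinates are (x, y) with y down (image convention): a point ``p`` in
    the moving image lands at ``matrix @ p + translation`` in the fixed
    frame.  ``quality`` is the Pearson correlation between the fixed image
    and the warped moving image.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    quality: float = 0.0
    degraded_to_identity: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(2)
        if not self.degraded_to_identity and abs(np.linalg.det(self.matrix)) <= 1e-6:
            raise ValueError("affine matrix is numerically singular")

    @classmethod
    def identity(cls, quality: float = 0.0, degraded: bool = False) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2), quality=quality, degraded_to_identity=degraded)

    def to_skimage(self) -> AffineTransform:
        params = np.eye(3)
        params[:2, :2] = self.matrix
        params[:2, 2] = self.translation
        return AffineTransform(matrix=params)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return AffineTransform2D(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
            quality=min(self.quality, other.quality),
        )

    def apply(self, image: PlanarImage, order: int = 1) -> PlanarImage:
        """Resample the moving image into the fixed frame (bilinear, 0-padded)."""
        warped = warp(
            np.asarray(image.intensities, dtype=np.float64),
            inverse_map=self.to_skimage().inverse,
            order=order,
            mode="constant",
            cval=0.0,
            preserve_range=True,
        )
        return PlanarImage(warped, image.pixel_size_um, kind=image.kind,
                           timepoint_min=image.timepoint_min)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def estimate_affine(moving: PlanarImage, fixed: PlanarImage) -> AffineTransform2D:
    """Estimate the affine transform aligning ``moving`` onto ``fixed``.

    SIFT keypoints are matched (mutual nearest neighbours with a ratio test)
    and a full affine model is fit by RANSAC.  The result is accepted only if
    it does not decrease the image correlation with ``fixed``; otherwise the
    identity is returned with ``degraded_to_identity=True`` and a warning
    logged.
    """
    if moving.intensities.shape != fixed.intensities.shape:
        raise ValueError("moving and fixed images must share dimensions")
    mov = np.asarray(moving.intensities, dtype=np.float64)
    fix = np.asarray(fixed.intensities, dtype=np.float64)
    base_quality = _pearson(mov, fix)
    if np.array_equal(mov, fix):
        return AffineTransform2D.identity(quality=1.0)

    try:
        det_m, det_f = SIFT(), SIFT()
        det_m.detect_and_extract(mov)
        det_f.detect_and_extract(fix)
        matches = match_descriptors(det_f.descriptors, det_m.descriptors,
                                    cross_check=True, max_ratio=0.8)
    except RuntimeError:  # SIFT found no keypoints (featureless image)
        matches = np.empty((0, 2), dtype=int)

    if len(matches) < MIN_INLIERS:
        log.warning("registration degraded to identity: only %d keypoint matches", len(matches))
        return AffineTransform2D.identity(quality=base_quality, degraded=True)

    # skimage keypoints are (row, col); the model works in (x, y)
    src = det_f.keypoints[matches[:, 0]][:, ::-1].astype(np.float64)  # fixed
    dst = det_m.keypoints[matches[:, 1]][:, ::-1].astype(np.float64)  # moving
    model, inliers = ransac(
        (dst, src),
        AffineTransform,
        min_samples=3,
        residual_threshold=1.0,
        max_trials=2000,
        rng=0,
    )
    if model is None or inliers is None or inliers.sum() < MIN_INLIERS:
        n = 0 if inliers is None else int(inliers.sum())
        log.warning("registration degraded to identity: only %d RANSAC inliers", n)
        return AffineTransform2D.identity(quality=base_quality, degraded=True)

    tform = AffineTransform2D(model.params[:2, :2], model.params[:2, 2])
    quality = _pearson(tform.apply(moving).intensities, fix)
    if quality < base_quality:
        log.warning(
            "registration degraded to identity: similarity %.3f < unregistered %.3f",
            quality, base_quality,
        )
        return AffineTransform2D.identity(quality=base_quality, degraded=True)
    tform.quality = quality
    return tform


def align_series(
    series: Timelapse, n_register: int | None = None
) -> tuple[Timelapse, list[AffineTransform2D]]:
    """Register frames 2..n_register to the first frame.

    Frames beyond ``n_register`` pass through unchanged with an identity
    transform flagged ``degraded_to_identity`` (they were never registered).
    Returns the aligned series and the per-frame transforms, which can also
    be applied to a second channel of the same timelapse.
    """
    n = len(series)
    if n_register is None:
        n_register = n
    if not 1 <= n_register <= n:
        raise ValueError(f"n_register must be in [1, {n}], got {n_register}")
    fixed = series.frames[0]
    aligned = [fixed]
    transforms = [AffineTransform2D.identity(quality=1.0)]
    for i, frame in enumerate(series.frames[1:], start=1):
        if i < n_register:
            tform = estimate_affine(frame, fixed)
            aligned.append(tform.apply(frame))
        else:
            tform = AffineTransform2D.identity(degraded=True)
            aligned.append(frame)
            log.info("frame %d beyond n_register=%d passed through unregistered", i, n_register)
        transforms.append(tform)
    return Timelapse(aligned, interval_min=series.interval_min), transforms


def average_projection(aligned: Timelapse) -> PlanarImage:
    """Pixelwise mean of the aligned frames, tagged as a contour image."""
    stack = np.stack([np.asarray(f.intensities, dtype=np.float64) for f in aligned.frames])
    mean = stack.mean(axis=0)
    first = aligned.frames[0]
    return PlanarImage(mean, first.pixel_size_um, kind="contour")
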