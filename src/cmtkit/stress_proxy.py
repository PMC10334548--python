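"""Geometry-based proxy for circumferential tensile stress around an ablation.

Ablating epidermal cells redirects tensile stress circumferentially around
the wound.  Rather than simulating mechanics, the expected stress orientation
is approximated purely geometrically: concentric 1-px contour lines are drawn
around the segmented ablation shape at a fixed spacing, and their local
orientation (measured with the same nematic-tensor statistic as the CMT
signal) serves as the per-cell reference angle.  This is a geometrical
feature, not a stress computation; anisotropy measured on these line images
is carried through the pipeline but is reference-only.

The normative contract is distance-transform level sets: line k is the 1-px
outer contour of the ablation shape dilated by ``k * spacing`` px, i.e. the
level set of the Euclidean distance transform at ``k * spacing``.  A concave
ablation can optionally be replaced by its convex hull first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image, diamond, thin

from .stack_io import PlanarImage

__all__ = ["ProxyLineImage", "make_proxy", "proxy_extent_um"]


@dataclass
class ProxyLineImage:
    """Binary image of concentric 1-px reference lines around the ablation."""

    lines: np.ndarray
    spacing_px: int
    n_lines: int
    pixel_size_um: float
    convex_hull_used: bool = False

    def __post_init__(self) -> None:
        self.lines = np.asarray(self.lines, dtype=bool)
        if self.spacing_px < 2:
            raise ValueError("spacing_px must be >= 2")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")

    def as_planar(self) -> PlanarImage:
        return PlanarImage(self.lines.astype(np.float64), self.pixel_size_um, kind="proxy")

    def extent_um(self) -> float:
        return proxy_extent_um(self.spacing_px, self.n_lines, self.pixel_size_um)


def _ring(dilated: np.ndarray) -> np.ndarray:
    """1-px inner boundary of a filled shape (4-neighbourhood erosion)."""
    ring = dilated & ~ndimage.binary_erosion(dilated, structure=diamond(1), border_value=1)
    # guard the 1-px-width invariant: collapse any residual 2x2 block
    if np.any(ring[:-1, :-1] & ring[:-1, 1:] & ring[1:, :-1] & ring[1:, 1:]):
        ring = thin(ring)
    return ring


def make_proxy(
    ablation_mask: np.ndarray,
    spacing_px: int = 16,
    n_lines: int = 6,
    use_convex_hull: bool = False,
    pixel_size_um: float = 1.0,
) -> ProxyLineImage:
    """Draw ``n_lines`` concentric contours around the ablation shape.

    Line k (k = 1..n_lines) sits at Euclidean distance ``k * spacing_px``
    from the (optionally convex-hulled) ablation; pixels inside the ablation
    stay 0 and image dimensions are unchanged.  Lines are drawn across the
    whole canvas even where they overlap other cells or get clipped by the
    border — downstream ROI intersection decides relevance.
    """
    mask = np.asarray(ablation_mask, dtype=bool)
    if not mask.any():
        raise ValueError("ablation mask is empty")
    if spacing_px < 2:
        raise ValueError("spacing_px must be >= 2")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if use_convex_hull:
        mask = convex_hull_image(mask)

    dist = ndimage.distance_transform_edt(~mask)
    lines = np.zeros_like(mask)
    for k in range(1, n_lines + 1):
        lines |= _ring(dist <= k * spacing_px)
    lines &= ~mask
    return ProxyLineImage(
        lines=lines,
        spacing_px=int(spacing_px),
        n_lines=int(n_lines),
        pixel_size_um=float(pixel_size_um),
        convex_hull_used=bool(use_convex_hull),
    )


def proxy_extent_um(spacing_px: int, n_lines: int, pixel_size_um: float) -> float:
    """Outward physical reach of the proxy: ``spacing * n_lines * pixel size``.

    Used as the default ROI trim distance so only signal within the proxy's
    reach (about one cell width in the published acquisition) is analyzed.
    """
    if spacing_px <= 0 or n_lines <= 0 or pixel_size_um <= 0:
        raise ValueError("all inputs must be positive")
    return float(spacing_px) * float(n_lines) * float(pixel_size_um)
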