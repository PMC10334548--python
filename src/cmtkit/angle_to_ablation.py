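"""Angle-to-ablation: pair CMT and proxy orientations and take the acute difference.

Orientations are axial (a fibril at theta and theta+180 deg are the same), so
the difference between a cell's CMT orientation and its local circumferential
reference is the acute angle in [0, 90]: 0 deg means perfectly
circumferential alignment, 90 deg perpendicular to the expected stress.
Paired per (cell, timepoint), the differences form the tidy record table that
all downstream statistics consume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .orientation_quantify import OrientationMeasure, render_quantification
from .stack_io import PlanarImage

__all__ = ["AngleRecord", "acute_angle_diff", "build_records", "render_a2a_overlay"]

log = logging.getLogger(__name__)


@dataclass
class AngleRecord:
    """One tidy row: a cell at a timepoint, with its angles and anisotropy.

    ``angle_to_ablation_deg`` is the acute difference between the CMT and
    proxy orientations whenever both are valid, NaN otherwise; ``anisotropy``
    comes from the CMT measure (proxy anisotropy is reference-only).
    """

    genotype: str
    condition: str  # "ablation" or "mock"
    sample: str
    cell_id: int
    timepoint_min: float
    cmt_angle_deg: float
    proxy_angle_deg: float
    angle_to_ablation_deg: float
    anisotropy: float

    def __post_init__(self) -> None:
        if self.condition not in ("ablation", "mock"):
            raise ValueError("condition must be 'ablation' or 'mock'")
        a2a = self.angle_to_ablation_deg
        if math.isfinite(a2a) and not (0.0 <= a2a <= 90.0):
            raise ValueError("angle_to_ablation_deg must lie in [0, 90]")
        if math.isfinite(self.anisotropy) and not (0.0 <= self.anisotropy <= 1.0 + 1e-12):
            raise ValueError("anisotropy must lie in [0, 1]")


def acute_angle_diff(a_deg: float, b_deg: float) -> float:
    """Acute difference between two axial orientations, in [0, 90].

    ``d = |a - b| mod 180; min(d, 180 - d)``.  NaN inputs propagate.
    """
    if not (math.isfinite(a_deg) and math.isfinite(b_deg)):
        return math.nan
    d = math.fmod(abs(a_deg - b_deg), 180.0)
    return min(d, 180.0 - d)


def build_records(
    cmt_measures: list[OrientationMeasure],
    proxy_measures: list[OrientationMeasure],
    metadata: dict,
) -> list[AngleRecord]:
    """Inner-join CMT and proxy measures on (cell_id, timepoint) into records.

    Unmatched keys are logged and dropped.  Invalid measures join normally
    and propagate NaN into the record (the row is retained so the tidy table
    stays one row per cell x timepoint).
    """
    for key in ("genotype", "condition", "sample"):
        if key not in metadata:
            raise ValueError(f"metadata missing {key!r}")

    def keyed(measures):
        return {(m.cell_id, m.timepoint_min): m for m in measures}

    cmt_by_key = keyed(cmt_measures)
    proxy_by_key = keyed(proxy_measures)
    common = sorted(cmt_by_key.keys() & proxy_by_key.keys(), key=lambda k: (k[1], k[0]))
    dropped = (cmt_by_key.keys() | proxy_by_key.keys()) - set(common)
    for key in sorted(dropped, key=str):
        log.info("unmatched (cell, timepoint) %s dropped from join", key)
    if not common:
        raise ValueError("empty join: no (cell_id, timepoint) pair has both measures")

    records = []
    for cell_id, tp in common:
        c = cmt_by_key[(cell_id, tp)]
        p = proxy_by_key[(cell_id, tp)]
        records.append(
            AngleRecord(
                genotype=str(metadata["genotype"]),
                condition=str(metadata["condition"]),
                sample=str(metadata["sample"]),
                cell_id=int(cell_id),
                timepoint_min=float(tp),
                cmt_angle_deg=c.angle_deg,
                proxy_angle_deg=p.angle_deg,
                angle_to_ablation_deg=acute_angle_diff(c.angle_deg, p.angle_deg),
                anisotropy=c.anisotropy,
            )
        )
    return records


def render_a2a_overlay(
    image: PlanarImage,
    cmt_measures: list[OrientationMeasure],
    proxy_measures: list[OrientationMeasure],
    records: list[AngleRecord],
    length_scale_px: float = 40.0,
) -> PlanarImage:
    """Composite overlay: CMT segments (magenta), proxy segments (green) and
    the per-cell angle difference printed in yellow, one decimal."""
    from PIL import Image, ImageDraw

    over = render_quantification(image, cmt_measures, color=(255, 0, 255), length_scale_px=length_scale_px)
    over = render_quantification(over, proxy_measures, color=(0, 255, 0), length_scale_px=length_scale_px)

    centroids = {m.cell_id: m.centroid_yx for m in cmt_measures if m.centroid_yx is not None}
    pil = Image.fromarray(over.intensities)
    draw = ImageDraw.Draw(pil)
    for rec in records:
        if not math.isfinite(rec.angle_to_ablation_deg):
            continue
        cyx = centroids.get(rec.cell_id)
        if cyx is None:
            continue
        draw.text((cyx[1] + 3, cyx[0] + 3), f"{rec.angle_to_ablation_deg:.1f}", fill=(255, 255, 0))
    return PlanarImage(np.asarray(pil), image.pixel_size_um, kind="overlay",
                       timepoint_min=image.timepoint_min)
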