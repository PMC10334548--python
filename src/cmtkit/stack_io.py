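"""Calibrated image containers and file I/O.

Every stage of the pipeline exchanges data through the three containers
defined here: :class:`VoxelGrid` (a 3D confocal stack for one timepoint),
:class:`PlanarImage` (any 2D image — projection, contour average, stress
proxy, label map or rendered overlay) and :class:`Timelapse` (an ordered,
co-calibrated series of either).

Conventions
-----------
Arrays are indexed ``(z, y, x)`` / ``(y, x)`` with the origin at the top-left
and y increasing downward (standard image convention).  Angles exported by the
quantification modules are converted to the mathematical convention (y up,
counter-clockwise positive) at measurement time; the containers themselves
never carry angles.

TIFF is the canonical on-disk format.  Calibration is read from standard
resolution tags or ImageJ-style metadata; an explicit override always wins.
The tidy table is CSV with ``.`` as decimal separator and NaN serialized as an
empty field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelGrid",
    "PlanarImage",
    "Timelapse",
    "read_stack",
    "write_stack",
    "read_planar",
    "write_planar",
    "write_tidy_table",
    "read_tidy_table",
    "TIDY_COLUMNS",
]

PlanarKind = Literal["projection", "contour", "proxy", "label", "overlay"]
_KINDS = ("projection", "contour", "proxy", "label", "overlay")

#: Column schema of the tidy per-cell table (one row per cell x timepoint).
TIDY_COLUMNS = (
    "genotype",
    "condition",
    "sample",
    "cell_id",
    "timepoint_min",
    "cmt_angle_deg",
    "proxy_angle_deg",
    "angle_to_ablation_deg",
    "anisotropy",
)


@dataclass
class VoxelGrid:
    """A calibrated 3D intensity volume for one timepoint.

    Parameters
    ----------
    intensities
        3D array indexed ``(z, y, x)``; finite and non-negative (boolean
        arrays are allowed for binarized volumes).
    voxel_size_um
        Physical voxel size ``(z, y, x)`` in micrometres, all positive.
    timepoint_min
        Acquisition time in minutes, or ``None`` when not part of a series.
    """

    intensities: np.ndarray
    voxel_size_um: tuple[float, float, float]
    timepoint_min: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"VoxelGrid requires a 3D (z, y, x) array, got ndim={self.intensities.ndim}"
            )
        if any(d < 1 for d in self.intensities.shape):
            raise ValueError("all VoxelGrid dimensions must be >= 1")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive values (z, y, x)")
        if self.intensities.dtype != bool:
            vals = self.intensities
            if not np.all(np.isfinite(vals)):
                raise ValueError("VoxelGrid intensities must be finite")
            if np.any(vals < 0):
                raise ValueError("VoxelGrid intensities must be non-negative")
        if self.timepoint_min is not None:
            self.timepoint_min = float(self.timepoint_min)
            if self.timepoint_min < 0:
                raise ValueError("timepoint_min must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class PlanarImage:
    """A calibrated 2D image.

    ``kind`` records the pipeline role of the image; ``kind="label"`` requires
    non-negative integer pixels and ``kind="overlay"`` may carry a trailing
    RGB axis.
    """

    intensities: np.ndarray
    pixel_size_um: float
    kind: PlanarKind = "projection"
    timepoint_min: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        nd_ok = self.intensities.ndim == 2 or (
            self.kind == "overlay" and self.intensities.ndim == 3 and self.intensities.shape[-1] in (3, 4)
        )
        if not nd_ok:
            raise ValueError("PlanarImage requires a 2D (y, x) array (or RGB for overlays)")
        if any(d < 1 for d in self.intensities.shape[:2]):
            raise ValueError("all PlanarImage dimensions must be >= 1")
        self.pixel_size_um = float(self.pixel_size_um)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "label":
            if not np.issubdtype(self.intensities.dtype, np.integer):
                raise ValueError("label images must have an integer dtype")
            if self.intensities.min(initial=0) < 0:
                raise ValueError("label images must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape


@dataclass
class Timelapse:
    """An ordered series of co-calibrated frames acquired at a fixed interval."""

    frames: list
    interval_min: float = 20.0

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("Timelapse requires at least one frame")
        self.interval_min = float(self.interval_min)
        if self.interval_min <= 0:
            raise ValueError("interval_min must be positive")
        first = self.frames[0]
        for fr in self.frames[1:]:
            if fr.intensities.shape != first.intensities.shape:
                raise ValueError("all Timelapse frames must share dimensions")
        times = [fr.timepoint_min for fr in self.frames if fr.timepoint_min is not None]
        if len(times) == len(self.frames) and any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise ValueError("frame timepoints must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def timepoints(self) -> list[float]:
        """Timepoints in minutes, inferred from the interval when absent."""
        return [
            fr.timepoint_min if fr.timepoint_min is not None else i * self.interval_min
            for i, fr in enumerate(self.frames)
        ]


# ---------------------------------------------------------------------------
# TIFF I/O


def _calibration_from_tiff(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """Return (xy_um, z_um) read from resolution tags / ImageJ metadata."""
    xy = z = None
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    if res is not None:
        num, den = res.value
        if num:
            xy = den / num  # pixels-per-unit -> unit-per-pixel
    meta = tif.imagej_metadata or {}
    if "spacing" in meta:
        z = float(meta["spacing"])
    return xy, z


def read_stack(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    timepoint_min: float | None = None,
) -> VoxelGrid:
    """Read a multi-page TIFF z-stack into a :class:`VoxelGrid`.

    Calibration is taken from the file's resolution tags (xy) and ImageJ
    ``spacing`` metadata (z); an explicit ``voxel_size_um`` override always
    wins.  A file carrying no calibration and no override is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        xy, z = _calibration_from_tiff(tif)
    if data.ndim != 3:
        raise ValueError(f"{path} has non-3D content (ndim={data.ndim}); expected a z-stack")
    if voxel_size_um is not None:
        size = voxel_size_um
    elif xy is not None and z is not None:
        size = (z, xy, xy)
    else:
        raise ValueError(
            f"{path} carries no voxel calibration; supply voxel_size_um explicitly"
        )
    return VoxelGrid(data, size, timepoint_min=timepoint_min)


def write_stack(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a :class:`VoxelGrid` as an ImageJ-style calibrated TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    z, y, x = grid.voxel_size_um
    data = grid.intensities
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if data.dtype == np.float64:
        data = data.astype(np.float32)  # ImageJ TIFF has no float64
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / x, 1.0 / y),
        metadata={"spacing": z, "unit": "um", "axes": "ZYX"},
    )
    return path


def write_planar(image: PlanarImage, path: str | Path) -> Path:
    """Write a :class:`PlanarImage` to TIFF (or PNG for RGB overlays).

    The pixel size is stored in the TIFF resolution tags so a read-back
    reproduces both values and calibration.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = image.intensities
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = data
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)
        return path
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    if np.issubdtype(data.dtype, np.signedinteger):
        if data.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("label values exceed uint16 range supported by ImageJ TIFF")
        data = data.astype(np.uint16)
    px = image.pixel_size_um
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / px, 1.0 / px),
        metadata={"unit": "um", "cmtkit_kind": image.kind},
    )
    return path


def read_planar(
    path: str | Path,
    pixel_size_um: float | None = None,
    kind: PlanarKind | None = None,
    timepoint_min: float | None = None,
) -> PlanarImage:
    """Read a 2D TIFF written by :func:`write_planar` (calibration round-trips)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        xy, _ = _calibration_from_tiff(tif)
        meta = tif.imagej_metadata or {}
    if kind is None:
        kind = meta.get("cmtkit_kind", "projection")
    if pixel_size_um is None:
        if xy is None:
            raise ValueError(f"{path} carries no pixel calibration; supply pixel_size_um")
        pixel_size_um = xy
    return PlanarImage(data, pixel_size_um, kind=kind, timepoint_min=timepoint_min)


# ---------------------------------------------------------------------------
# Tidy table


def write_tidy_table(records: Sequence, path: str | Path) -> Path:
    """Write AngleRecords as the tidy per-cell CSV (one row per cell x timepoint).

    NaN values (flagged cells) are serialized as empty fields; the row is
    retained so the record count stays one per (cell, timepoint).
    """
    if len(records) == 0:
        raise ValueError("cannot write an empty record list")
    frame = records_to_frame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep="")
    return path


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert AngleRecords (or dicts) to a DataFrame with the tidy schema."""
    rows = []
    for rec in records:
        if isinstance(rec, dict):
            rows.append({c: rec.get(c, math.nan) for c in TIDY_COLUMNS})
        else:
            rows.append({c: getattr(rec, c) for c in TIDY_COLUMNS})
    return pd.DataFrame(rows, columns=list(TIDY_COLUMNS))


def read_tidy_table(path: str | Path) -> list:
    """Read a tidy CSV back into AngleRecords (empty fields become NaN)."""
    from .angle_to_ablation import AngleRecord

    frame = pd.read_csv(path)
    missing = set(TIDY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"tidy table {path} is missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            AngleRecord(
                genotype=str(row.genotype),
                condition=str(row.condition),
                sample=str(row.sample),
                cell_id=int(row.cell_id),
                timepoint_min=float(row.timepoint_min),
                cmt_angle_deg=float(row.cmt_angle_deg) if pd.notna(row.cmt_angle_deg) else math.nan,
                proxy_angle_deg=float(row.proxy_angle_deg) if pd.notna(row.proxy_angle_deg) else math.nan,
                angle_to_ablation_deg=float(row.angle_to_ablation_deg)
                if pd.notna(row.angle_to_ablation_deg)
                else math.nan,
                anisotropy=float(row.anisotropy) if pd.notna(row.anisotropy) else math.nan,
            )
        )
    return records
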