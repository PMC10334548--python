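"""Batch pipeline over an Experiment/Genotype/Sample folder tree.

Ties the stages together non-interactively: surface extraction (for 3D stack
input) -> contour registration and averaging -> watershed segmentation ->
ablation designation -> ROI erosion and trimming -> stress proxy ->
orientation quantification of both channels -> angle-to-ablation records ->
summary statistics.  Every interactive step of the original toolset
(ablation click, segmentation correction) is a config entry: an ablation
point/id/merge-list per sample, an optional marker image, and excluded-cell
lists.

One sample's failure is logged and skipped; the batch continues.  With a
fixed config and seed the outputs are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import angle_to_ablation as a2a
from . import orientation_quantify as oq
from . import segmentation_roi as seg
from . import stress_proxy as sp
from . import summary_stats as stats
from . import surface_extraction as surf
from . import timelapse_preprocess as prep
from .stack_io import PlanarImage, Timelapse, read_planar, read_stack, records_to_frame, write_planar, write_tidy_table

__all__ = [
    "StageParams",
    "SampleSpec",
    "PipelineConfig",
    "init_tree",
    "process_sample",
    "run_all",
    "STAGE_DIRS",
]

log = logging.getLogger(__name__)

STAGE_DIRS = ("stacks", "projected", "preproc", "labels", "rois", "proxy", "quantify", "a2a", "stats", "logs")


@dataclass
class StageParams:
    """Per-stage parameter block (defaults mirror the reference protocol)."""

    # surface extraction
    blur_sigma_px: float = 3.0
    threshold: float = 0.3
    cmt_shell: tuple[int, int] = (0, 4)
    contour_shell: tuple[int, int] = (4, 10)
    projector: str = "max"
    # registration
    n_register: int | None = None
    # segmentation
    smooth_sigma_px: float = 2.0
    h_min: float = 0.1
    # ROI construction
    erode_iterations: int = 3
    erode_radius_px: int = 1
    max_gap_px: int = 2
    trim_um: float | None = None  # None -> proxy extent
    # stress proxy
    proxy_spacing_px: int = 16
    proxy_n_lines: int = 6
    proxy_convex_hull: bool = False
    # statistics
    n_boot: int = 1000
    ci_level: float = 0.95

    def trim_distance_um(self, pixel_size_um: float) -> float:
        if self.trim_um is not None:
            return self.trim_um
        return sp.proxy_extent_um(self.proxy_spacing_px, self.proxy_n_lines, pixel_size_um)


@dataclass
class SampleSpec:
    """One sample: identity, condition, and its non-interactive selectors."""

    genotype: str
    sample: str
    condition: str = "ablation"
    ablation_point: tuple[float, float] | None = None
    ablation_id: int | None = None
    mock_ids: list[int] | None = None
    #: points (x, y) whose labels are merged into a pseudo-ablation — the
    #: scriptable equivalent of clicking the mock-ablation cell group
    mock_points: list[tuple[float, float]] | None = None
    excluded_cells: list[int] = field(default_factory=list)

    @property
    def key(self) -> str:
        return f"{self.genotype}/{self.sample}"

    def n_selectors(self) -> int:
        return sum(
            x is not None
            for x in (self.ablation_point, self.ablation_id, self.mock_ids, self.mock_points)
        )


@dataclass
class PipelineConfig:
    root: Path
    samples: list[SampleSpec]
    params: StageParams = field(default_factory=StageParams)
    seed: int = 0
    pixel_size_um: float | None = None  # override when files carry no calibration

    def validate(self) -> None:
        """Check parameters before any processing.

        Missing sample directories and ambiguous (multiple) selectors are
        hard errors; a sample with *no* ablation selector is allowed here and
        skipped at run time with a log entry, so one unconfigured sample does
        not block the batch.
        """
        missing = [s.key for s in self.samples if not (self.root / s.genotype / s.sample).is_dir()]
        if missing:
            raise ValueError(f"sample directories missing under {self.root}: {missing}")
        for s in self.samples:
            if s.n_selectors() > 1:
                raise ValueError(f"sample {s.key} has multiple ablation selectors")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        params = StageParams(**{k: _tuplify(k, v) for k, v in (raw.get("stages") or {}).items()})
        samples = []
        for key, spec in (raw.get("samples") or {}).items():
            genotype, sample = key.split("/", 1)
            spec = dict(spec or {})
            point = spec.pop("ablation_point", None)
            mock_points = spec.pop("mock_points", None)
            samples.append(
                SampleSpec(
                    genotype=genotype,
                    sample=sample,
                    condition=spec.pop("condition", "ablation"),
                    ablation_point=tuple(point) if point is not None else None,
                    ablation_id=spec.pop("ablation_id", None),
                    mock_ids=spec.pop("mock_ids", None),
                    mock_points=[tuple(p) for p in mock_points] if mock_points else None,
                    excluded_cells=list(spec.pop("excluded_cells", []) or []),
                )
            )
        root = Path(raw.get("root", path.parent))
        if not root.is_absolute():
            root = (path.parent / root).resolve()
        return cls(
            root=root,
            samples=samples,
            params=params,
            seed=int(raw.get("seed", 0)),
            pixel_size_um=raw.get("pixel_size_um"),
        )


def _tuplify(key: str, value):
    return tuple(value) if key in ("cmt_shell", "contour_shell") and value is not None else value


def init_tree(root: str | Path, genotypes: list[str], samples: list[str], force: bool = False) -> Path:
    """Create the Experiment/Genotype/Sample tree with stage subfolders.

    Refuses to touch an existing non-empty root unless ``force`` is given;
    with ``force`` the operation is idempotent.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(f"{root} exists and is not empty (use force=True to reuse)")
    for g in genotypes:
        for s in samples:
            for stage in STAGE_DIRS:
                (root / g / s / stage).mkdir(parents=True, exist_ok=True)
    return root


# ---------------------------------------------------------------------------
# Core per-sample computation (pure in-memory; folder I/O lives in run_all)


def process_sample(
    cmt_series: Timelapse,
    contour_series: Timelapse,
    spec: SampleSpec,
    params: StageParams,
    marker_image: np.ndarray | None = None,
) -> dict:
    """Run segmentation, proxy and quantification for one sample.

    The contour frames are registered to the first frame and averaged; the
    per-frame transforms are applied to the CMT frames as well, so the single
    ROI set derived from the averaged contour stays aligned with every
    timepoint.  Returns a dict with the records and all intermediate
    artifacts (labels, roi_set, proxy, transforms).
    """
    aligned_contour, transforms = prep.align_series(contour_series, params.n_register)
    contour_avg = prep.average_projection(aligned_contour)
    aligned_cmt = Timelapse(
        [t.apply(f) if not t.degraded_to_identity else f
         for t, f in zip(transforms, cmt_series.frames)],
        interval_min=cmt_series.interval_min,
    )

    labels = seg.segment_cells(contour_avg, params.smooth_sigma_px, params.h_min, markers=marker_image)
    mock_ids = spec.mock_ids
    if spec.mock_points is not None:
        # resolve the clicked-equivalent points to label ids post-segmentation
        mock_ids = sorted(
            {int(labels.labels[int(round(y)), int(round(x))]) for x, y in spec.mock_points}
        )
        if 0 in mock_ids:
            raise ValueError("a mock point lies on a watershed boundary (label 0)")
    labels, ablation_id = seg.select_ablation(
        labels,
        point_xy=spec.ablation_point,
        label_id=spec.ablation_id,
        mock_ids=mock_ids,
    )
    trim_um = params.trim_distance_um(contour_avg.pixel_size_um)
    roi_set = seg.build_roi_set(
        labels,
        ablation_id,
        trim_distance_um=trim_um,
        max_gap_px=params.max_gap_px,
        erode_iterations=params.erode_iterations,
        erode_radius_px=params.erode_radius_px,
        excluded_cells=spec.excluded_cells,
    )

    proxy = sp.make_proxy(
        roi_set.ablation_mask,
        spacing_px=params.proxy_spacing_px,
        n_lines=params.proxy_n_lines,
        use_convex_hull=params.proxy_convex_hull,
        pixel_size_um=contour_avg.pixel_size_um,
    )
    proxy_img = proxy.as_planar()

    metadata = {"genotype": spec.genotype, "condition": spec.condition, "sample": spec.sample}
    records = []
    cmt_measures_all, proxy_measures_all = [], []
    # the proxy image is static across the timelapse: measure once, re-stamp
    proxy_template = oq.quantify_rois(proxy_img, roi_set, source_tag="proxy")
    for frame, t in zip(aligned_cmt.frames, aligned_cmt.timepoints()):
        cmt_measures = oq.quantify_rois(frame, roi_set, source_tag="cmt", timepoint_min=t)
        proxy_measures = [dataclasses.replace(m, timepoint_min=t) for m in proxy_template]
        records.extend(a2a.build_records(cmt_measures, proxy_measures, metadata))
        cmt_measures_all.append(cmt_measures)
        proxy_measures_all.append(proxy_measures)

    return {
        "records": records,
        "labels": labels,
        "ablation_id": ablation_id,
        "roi_set": roi_set,
        "proxy": proxy,
        "transforms": transforms,
        "contour_avg": contour_avg,
        "aligned_cmt": aligned_cmt,
        "cmt_measures": cmt_measures_all,
        "proxy_measures": proxy_measures_all,
        "trim_um": trim_um,
    }


# ---------------------------------------------------------------------------
# Folder-tree batch driver


def _load_sample_series(sample_dir: Path, params: StageParams, pixel_size_um, interval_min=20.0):
    """Load a sample's timelapse: 3D stacks (run surface extraction) or
    pre-projected 2D cmt/contour pairs."""
    stack_paths = sorted((sample_dir / "stacks").glob("*.tif"))
    if stack_paths:
        cmt_frames, contour_frames = [], []
        cmt_shell = surf.ShellParams(params.blur_sigma_px, params.threshold, *params.cmt_shell)
        con_shell = surf.ShellParams(params.blur_sigma_px, params.threshold, *params.contour_shell)
        for i, p in enumerate(stack_paths):
            size = (None if pixel_size_um is None
                    else (0.5, pixel_size_um, pixel_size_um))
            grid = read_stack(p, voxel_size_um=size, timepoint_min=i * interval_min)
            c, k = surf.surfcut(grid, cmt=cmt_shell, contour=con_shell, projector=params.projector)
            cmt_frames.append(c)
            contour_frames.append(k)
        return Timelapse(cmt_frames, interval_min), Timelapse(contour_frames, interval_min)
    cmt_paths = sorted((sample_dir / "projected").glob("cmt_*.tif"))
    con_paths = sorted((sample_dir / "projected").glob("contour_*.tif"))
    if not cmt_paths or len(cmt_paths) != len(con_paths):
        raise FileNotFoundError(
            f"{sample_dir}: expected stacks/*.tif or matching projected/cmt_*.tif + contour_*.tif"
        )
    cmt_frames = [read_planar(p, pixel_size_um=pixel_size_um, timepoint_min=i * interval_min)
                  for i, p in enumerate(cmt_paths)]
    con_frames = [read_planar(p, pixel_size_um=pixel_size_um, kind="contour", timepoint_min=i * interval_min)
                  for i, p in enumerate(con_paths)]
    return Timelapse(cmt_frames, interval_min), Timelapse(con_frames, interval_min)


def run_all(config: PipelineConfig, write_plots: bool = True) -> pd.DataFrame:
    """Execute the full pipeline for every configured sample.

    Writes per-sample artifacts and logs under each sample directory, the
    combined tidy CSV and summary tables (genotype and sample level, both
    metrics) under ``root/stats``.  A failing sample is logged and skipped.
    Returns the combined tidy record table.
    """
    config.validate()
    all_records = []
    for spec in config.samples:
        sample_dir = config.root / spec.genotype / spec.sample
        if spec.n_selectors() == 0:
            log.warning("sample %s has no ablation selector; skipped", spec.key)
            continue
        try:
            cmt_series, contour_series = _load_sample_series(
                sample_dir, config.params, config.pixel_size_um
            )
            marker = None
            marker_path = sample_dir / "markers.tif"
            if marker_path.exists():
                marker = read_planar(marker_path, pixel_size_um=1.0).intensities
            result = process_sample(cmt_series, contour_series, spec, config.params, marker_image=marker)
        except Exception:
            log.exception("sample %s failed; continuing with remaining samples", spec.key)
            continue
        _write_sample_outputs(sample_dir, spec, config, result)
        all_records.extend(result["records"])

    if not all_records:
        raise RuntimeError("no sample completed successfully")
    combined = records_to_frame(all_records)
    stats_dir = config.root / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    combined.to_csv(stats_dir / "all_records.csv", index=False, na_rep="")

    bconf = stats.BootstrapConfig(n_boot=config.params.n_boot, level=config.params.ci_level, seed=config.seed)
    for level in ("genotype", "sample"):
        for metric in ("angle_to_ablation", "anisotropy"):
            table = stats.summarize(combined, level=level, metric=metric, config=bconf)
            table.to_csv(stats_dir / f"summary_{level}_{metric}.csv", index=False)
            if write_plots and level == "genotype":
                stats.plot_summary(table, stats_dir / f"summary_{metric}.png")
    return combined


def _write_sample_outputs(sample_dir: Path, spec: SampleSpec, config: PipelineConfig, result: dict) -> None:
    labels = result["labels"]
    write_planar(PlanarImage(labels.labels.astype(np.int32), labels.pixel_size_um, kind="label"),
                 sample_dir / "labels" / "cells.tif")
    write_planar(result["proxy"].as_planar(), sample_dir / "proxy" / "proxy.tif")
    write_planar(result["contour_avg"], sample_dir / "preproc" / "contour_avg.tif")
    roi_set = result["roi_set"]
    if roi_set.trimmed_masks:
        roi_stack = np.stack([roi_set.trimmed_masks[c] for c in sorted(roi_set.trimmed_masks)])
        import tifffile

        (sample_dir / "rois").mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(sample_dir / "rois" / "trimmed_masks.tif", roi_stack.astype(np.uint8))
    write_tidy_table(result["records"], sample_dir / "a2a" / "records.csv")

    run_log = {
        "sample": spec.key,
        "condition": spec.condition,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config.params),
        "ablation_id": result["ablation_id"],
        "trim_um": result["trim_um"],
        "n_cells": len(roi_set.cell_masks),
        "excluded_cells": roi_set.excluded_ids,
        "registration": [
            {"quality": round(t.quality, 4), "degraded_to_identity": t.degraded_to_identity}
            for t in result["transforms"]
        ],
    }
    (sample_dir / "logs").mkdir(parents=True, exist_ok=True)
    (sample_dir / "logs" / "run.json").write_text(json.dumps(run_log, indent=2))
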