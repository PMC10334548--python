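"""Group summaries with percentile-bootstrap confidence intervals.

Per-cell angle-to-ablation and anisotropy trajectories are aggregated per
genotype/condition/timepoint (or per sample, or reported raw per cell) as the
arithmetic mean with a bootstrapped 95% confidence interval (1000 resamples
of cell-level values by default).  The CI is used as an estimate of
difference, not a significance test — no hypothesis testing is exposed.

Unlike typical plotting-library defaults, resampling is seeded, so repeated
runs are bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack_io import records_to_frame

__all__ = ["BootstrapConfig", "bootstrap_ci", "summarize", "plot_summary", "round_for_report"]

_LEVEL_KEYS = {
    "genotype": ["genotype", "condition"],
    "sample": ["genotype", "condition", "sample"],
    "cell": ["genotype", "condition", "sample", "cell_id"],
}


@dataclass
class BootstrapConfig:
    """Percentile-bootstrap settings: resample count, CI level, RNG seed."""

    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")


def bootstrap_ci(values, config: BootstrapConfig | None = None) -> tuple[float, float, float]:
    """Mean and percentile-bootstrap CI of the mean.

    Resamples ``len(values)`` values with replacement ``n_boot`` times and
    takes the ``[(1-level)/2, 1-(1-level)/2]`` percentiles of the resampled
    means.  NaNs are dropped first; an empty or all-NaN input is an error.
    """
    config = config or BootstrapConfig()
    vals = np.asarray(values, dtype=np.float64)
    vals = vals[np.isfinite(vals)]
    n = vals.size
    if n == 0:
        raise ValueError("bootstrap_ci requires at least one finite value")
    mean = float(vals.mean())
    if n == 1 or np.ptp(vals) == 0.0:
        return mean, mean, mean  # degenerate resampling is exact
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n, size=(config.n_boot, n))
    boot_means = vals[idx].mean(axis=1)
    alpha = (1.0 - config.level) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha])
    return mean, float(lo), float(hi)


def summarize(
    records,
    level: str = "genotype",
    metric: str = "angle_to_ablation",
    config: BootstrapConfig | None = None,
) -> pd.DataFrame:
    """Aggregate records per group x timepoint with mean and bootstrap CI.

    ``level`` is one of ``genotype`` (pooling all cells of a genotype x
    condition), ``sample`` or ``cell``; at the cell level the raw trajectory
    is reported (mean = value, no CI).  ``metric`` is ``angle_to_ablation``
    or ``anisotropy``.  NaN records are excluded from n.  Each group gets an
    independent bootstrap stream derived from the config seed, so results do
    not depend on group iteration order.
    """
    if level not in _LEVEL_KEYS:
        raise ValueError(f"unknown level {level!r}; expected one of {sorted(_LEVEL_KEYS)}")
    col = {"angle_to_ablation": "angle_to_ablation_deg", "anisotropy": "anisotropy"}.get(metric)
    if col is None:
        raise ValueError(f"unknown metric {metric!r}")
    config = config or BootstrapConfig()

    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to summarize")
    keys = _LEVEL_KEYS[level] + ["timepoint_min"]

    rows = []
    for group_vals, grp in frame.groupby(keys, sort=True):
        vals = grp[col].to_numpy(dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        row = dict(zip(keys, group_vals))
        row["metric"] = metric
        if vals.size == 0:
            row.update(mean=np.nan, ci_low=np.nan, ci_high=np.nan, n=0)
        elif level == "cell":
            row.update(mean=float(vals.mean()), ci_low=np.nan, ci_high=np.nan, n=int(vals.size))
        else:
            # stable per-group seed so group order is irrelevant across runs
            key_bytes = "|".join(str(v) for v in group_vals).encode()
            gseed = (config.seed + zlib.crc32(key_bytes)) % (2**31)
            gconf = BootstrapConfig(n_boot=config.n_boot, level=config.level, seed=gseed)
            # sort so the resampling stream is invariant to record order
            mean, lo, hi = bootstrap_ci(np.sort(vals), gconf)
            row.update(mean=mean, ci_low=lo, ci_high=hi, n=int(vals.size))
        rows.append(row)
    return pd.DataFrame(rows)


def round_for_report(stats: pd.DataFrame) -> pd.DataFrame:
    """Round for report text: angles to whole degrees, anisotropy to 2 decimals."""
    out = stats.copy()
    digits = np.where(out["metric"] == "anisotropy", 2, 0)
    for col in ("mean", "ci_low", "ci_high"):
        out[col] = [round(v, int(d)) if np.isfinite(v) else v for v, d in zip(out[col], digits)]
    return out


def plot_summary(stats: pd.DataFrame, output_path, title: str | None = None):
    """Line plot of group mean vs timepoint with a shaded CI band.

    One line per (genotype, condition); the ablation/mock distinction follows
    the published colour scheme (blue = ablation, orange = mock).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if stats.empty:
        raise ValueError("empty summary table")
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"ablation": "tab:blue", "mock": "tab:orange"}
    group_cols = [c for c in ("genotype", "condition", "sample", "cell_id") if c in stats.columns]
    for group_vals, grp in stats.groupby(group_cols, sort=True):
        grp = grp.sort_values("timepoint_min")
        label = "/".join(str(v) for v in (group_vals if isinstance(group_vals, tuple) else (group_vals,)))
        cond = grp["condition"].iloc[0] if "condition" in grp else None
        color = colors.get(cond)
        (line,) = ax.plot(grp["timepoint_min"], grp["mean"], label=label, color=color)
        if grp["ci_low"].notna().any():
            ax.fill_between(grp["timepoint_min"], grp["ci_low"], grp["ci_high"],
                            alpha=0.25, color=line.get_color())
    metric = stats["metric"].iloc[0]
    ax.set_xlabel("time (min)")
    ax.set_ylabel("angle to ablation (deg)" if metric == "angle_to_ablation" else "anisotropy")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(output_path, dpi=120)
    plt.close(fig)
    return output_path
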