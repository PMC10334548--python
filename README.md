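# cmtkit

Quantify how cortical microtubule (CMT) arrays reorient around a wound.

When a few epidermal cells of a plant organ are ablated, tensile stress in
the surrounding tissue redirects circumferentially around the wound, and the
CMT arrays of the neighbouring cells progressively align with it.  `cmtkit`
turns 3D confocal timelapse stacks of a microtubule reporter into per-cell
trajectories of two numbers:

- **angle to ablation** — the acute difference, in [0°, 90°], between a
  cell's mean CMT orientation and the local circumferential direction
  (0° = perfectly circumferential, 90° = perpendicular to the expected
  stress), and
- **anisotropy** — how co-aligned the CMT signal is, in [0, 1].

It is written for plant cell biologists running ablation (or mock-ablation)
timelapse experiments who want a scriptable, deterministic alternative to
interactive image-analysis toolchains — every manual step (clicking the
ablation, correcting a segmentation) is replaced by a config entry.

## The measurement

Orientation and anisotropy come from the intensity-gradient **nematic
tensor**.  For each ROI pixel, the local fibril tangent is the image gradient
rotated by 90°, `t = (−I_y, I_x)/|∇I|`; averaging its outer product over the
ROI gives

```
T = ⟨ t tᵀ ⟩,   trace(T) = 1
```

whose principal eigenvector is the mean orientation and whose eigenvalue
difference `λ₁ − λ₂ ∈ [0, 1]` is the anisotropy.

The circumferential reference is not a mechanical simulation but a
**geometry-based proxy**: concentric 1-px contour lines drawn at the level
sets of the Euclidean distance transform of the segmented ablation shape
(optionally its convex hull), measured with the same nematic tensor.

The pipeline stages (each usable alone, `cmtkit <stage> --help`):

1. `surfcut` — detect the sample surface per image column in the z-stack and
   project a shallow shell (CMT signal) and a deeper shell (cell contours).
2. `preproc` — register every contour frame to the first (SIFT + RANSAC
   affine) and average, sharpening the contour signal.
3. `segment` — marker-controlled watershed of the averaged contour image;
   the ablation label is picked by point/id/merge-list; the row of cells
   bordering it is selected by region adjacency, eroded 3× (radius 1 px) to
   drop edge signal and trimmed to a fixed distance (default: the proxy
   extent, ~30 µm) from the ablation.
4. `proxy` — draw the circumferential stress proxy.
5. `quantify` / `a2a` — nematic-tensor measures for both channels, paired
   per cell × timepoint into a tidy CSV.
6. `stats` — group means with seeded percentile-bootstrap 95% confidence
   intervals (n = 1000 resamples), per genotype, sample or cell, plus plots.

`run-all` executes everything over an `Experiment/Genotype/Sample` folder
tree from one YAML config; `simulate` generates synthetic tissue with known
ground truth.

## Worked example

Generate a synthetic ablation timelapse whose cells start 45° away from the
circumferential direction and relax toward it with a 80-min time constant,
run the full pipeline on it, and summarize:

```python
import numpy as np
from cmtkit import SyntheticScenario, make_tissue_timelapse, summarize, BootstrapConfig
from cmtkit.pipeline import SampleSpec, StageParams, process_sample
from cmtkit.stack_io import records_to_frame

scenario = SyntheticScenario(seed=1)          # a0=45 deg, tau=80 min, 13 x 20 min
cmt, contour, truth = make_tissue_timelapse(scenario)

ys, xs = np.nonzero(scenario.ablation_mask())
spec = SampleSpec("GFP-MBD", "s1", "ablation",
                  ablation_point=(xs.mean(), ys.mean()))
result = process_sample(cmt, contour, spec, StageParams(n_register=1))

records = records_to_frame(result["records"])
table = summarize(records, level="genotype", metric="angle_to_ablation",
                  config=BootstrapConfig(seed=0))
print(table[["timepoint_min", "mean", "ci_low", "ci_high", "n"]].round(1).to_string(index=False))
```

```
 timepoint_min  mean  ci_low  ci_high  n
           0.0  44.9    44.7     45.1 12
          20.0  34.8    34.6     35.1 12
          40.0  27.1    26.9     27.4 12
          ...
         120.0   9.9     9.7     10.1 12
          ...
         240.0   2.1     2.0      2.3 12
```

The 12 cells adjacent to the ablation start at the programmed 45° offset and
decay along `45·exp(−t/80 min)` — the pipeline recovers 2.1° at 240 min
against the analytic 45·e⁻³ ≈ 2.2°.  Each row's CI is the percentile
bootstrap over cells.

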