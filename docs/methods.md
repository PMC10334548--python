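# Methods

This note documents the models, conventions, numerical choices and known
limitations of `cmtkit`.  It is the place where design decisions that were
genuinely open are recorded.

## Coordinate and angle conventions

Arrays are indexed `(z, y, x)` / `(y, x)`, origin top-left, y down.  All
reported angles use the mathematical convention — degrees counter-clockwise
from +x with y up, mapped to (−90°, 90°] — obtained by negating the y
component of image-space vectors at measurement time.  Orientations are
axial (θ and θ+180° are identical); differences between orientations are
therefore acute angles in [0°, 90°], computed as
`min(d, 180 − d)` with `d = |a − b| mod 180`.

## Surface-shell projection

The epidermal CMT signal lives in a thin shell under the sample surface.
The stack is Gaussian-blurred in xy only (voxels are strongly anisotropic:
0.31 µm laterally vs 0.5 µm axially in the reference acquisition, and the
surface is sought per xy column), thresholded, and the first supra-threshold
voxel per column defines the surface depth map.  A shell `[depth + top,
depth + bottom)` is then projected per column (max by default — appropriate
for sparse fluorescent structures; mean is available for contour averaging).
Two presets exist: `cmt` (slices 0–4 below the surface) and `contour`
(slices 4–10).  These depths, and the blur/threshold, are dataset-tunable
parameters, not constants of the method.

No geometric unfolding is attempted.  A 2D projection distorts signal on
steep flanks; the downstream 3× ROI erosion drops most cell-edge signal,
which is exactly the signal most oblique to the projection.  Analyses should
still prefer ablations on surfaces roughly parallel to the imaging plane.

## Registration and contour averaging

Each contour frame is registered to the first frame with a full 2D affine
model estimated from SIFT keypoint matches (mutual nearest neighbours,
ratio 0.8) by RANSAC (residual 1 px, seeded).  A transform is accepted only
if it has ≥ 6 inliers *and* does not decrease the Pearson correlation to the
reference frame; otherwise the frame falls back to the identity and is
flagged — a failed registration never aborts the batch.  Resampling is
bilinear with zero padding.

One open design point was whether the registered frames or only their
average feed the rest of the pipeline.  Here the **single averaged contour
image defines one segmentation**, whose ROI set is applied to every
timepoint; the per-frame transforms estimated on the contour channel are
also applied to the matching CMT frames so that the static ROI set stays
aligned with each timepoint.  This makes cell identity across timepoints
stable by construction, at the cost of assuming the tissue deforms little
over the series — fast-growing or dividing samples are out of scope.

## Segmentation and ROI construction

Cells are obtained by marker-controlled watershed of the smoothed contour
image (markers: regional minima surviving depth-`h` suppression; ridge lines
labelled 0, 1 px wide).  The watershed implementation is deterministic, so
identical inputs give identical labels.  Interactive correction is replaced
by two overrides: an explicit marker image, and label merge lists.

The ablation is designated by a point, a label id, or — for mock
experiments — a list of points/ids whose labels are merged into one
pseudo-ablation (internal watershed lines are absorbed when all their
neighbours belong to the merged group).

Neighbour selection uses a Chebyshev distance criterion: a cell is adjacent
if any of its pixels lies within `max_gap_px` (default 2) of an ablation
pixel.  The 2-px default bridges the 1-px watershed line and *includes*
corner-touching cells; setting 1 excludes them.  Selected cells are eroded
`3×` with a radius-1 diamond (4-neighbourhood) structuring element and then
trimmed to a fixed physical distance from the ablation (exact Euclidean
distance transform; default distance = the proxy extent, ~30 µm at the
reference calibration, about one cell width).  Cells eroded or trimmed to
empty are excluded and logged.  The nesting `trimmed ⊆ eroded ⊆ region` is
asserted at construction.

## Circumferential stress proxy

The proxy is *not* a stress computation; it is a geometrical reference built
on the assumption that wound-induced stress is circumferential and locally
dominates pre-existing stress fields.  Its normative contract is:
line k (k = 1..n) is the 1-px contour of the ablation shape dilated by
`k · spacing` px, i.e. the level set of the Euclidean distance transform at
`k · spacing`.  The **outer** contour (4-neighbourhood inner boundary of the
dilated set) was chosen over the inner one; the difference is ±1 px.  A
residual 2×2 block, if the discrete boundary ever produces one, is thinned
away to preserve the 1-px-width invariant.  Lines are drawn across the whole
canvas (clipped at borders); ROI intersection decides relevance downstream.
Concave ablations can first be replaced by their convex hull.  Anisotropy
measured on proxy images is carried through but is reference-only; only the
angles are meaningful.

Defaults: spacing 16 px × 6 lines, which at 0.31 µm/px gives a 29.76 µm
outward extent and doubles as the default ROI trim distance.

## Orientation and anisotropy

See the README for the nematic-tensor definition.  Numerical choices:

- **Gradient stencil.** Derivatives use a rotation-optimized Scharr-type
  3×3 stencil: central difference along the axis with 3/16–10/16–3/16
  smoothing across it.  Plain central differences bias the recovered
  orientation of an 8-px-wavelength stripe pattern by up to ~1.4°
  (direction-dependent sinc attenuation); the Scharr weighting reduces this
  below 0.15°, keeping noiseless stripe recovery within the 1° tolerance the
  test suite demands.  Bit-exact parity with any particular plugin is not
  promised, only tolerance-level agreement.
- Pixels with zero gradient are excluded from the tensor average rather than
  assigned an arbitrary tangent; a ROI with no contributing pixel yields an
  invalid (NaN) measure that propagates as NaN through records and is
  excluded from group n.
- Only pixels whose full 3×3 neighbourhood is in-bounds contribute; ROI
  masks are already eroded away from cell edges, so this costs nothing in
  practice.

## Records and statistics

CMT and proxy measures are inner-joined on (cell, timepoint); anisotropy is
taken from the CMT side.  The tidy CSV has one row per cell × timepoint with
NaN serialized as an empty field.

Summaries are the arithmetic mean with a **percentile bootstrap** CI of the
mean (default 1000 resamples, 95%), the resampling unit being the cell-level
record — matching how per-cell n is reported in this kind of experiment,
and deliberately ignoring within-sample correlation (a hierarchical,
sample-level resampling could be added, but the reference analysis pools
cells).  No hypothesis tests are exposed; the CI is an estimate of
difference.  Unlike typical plotting-library defaults the bootstrap is
seeded: each group draws from a stream derived from the global seed and a
CRC of the group key, and group values are sorted first, so results are
independent of record order and bit-reproducible.  Degenerate inputs (n = 1
or zero variance) return an exact zero-width interval.  Report rounding
follows the field convention: angles to whole degrees, anisotropies to two
decimals.

## Synthetic data: what it does and does not emulate

The generator renders a grid of cells (default 5×5, 97-px ≈ 30 µm cells at
0.31 µm/px) separated by bright walls, with a block of cells (default 2×2,
mirroring a ~4-cell manual ablation) darkened as the wound.  Each intact
cell carries a sinusoidal stripe field whose orientation relaxes toward the
local circumferential direction as

```
angle_to_circumferential(t) = a0 · exp(−t / tau)
```

with defaults a0 = 45°, tau = 80 min over 13 timepoints × 20 min (the angle
plateaus by ~120–160 min, as in the real response), and whose alignment is
programmed as a linear stripe-weight ramp (0.5 → 0.9) against an isotropic
floor, emulating the anisotropy rise.  τ = ∞ freezes the dynamics; τ = 0 is
the instant-relaxation limit (offset a0 at t = 0, circumferential from t₁).
The mock condition keeps the tissue intact, draws frozen uniform random
orientations, and designates the central block as pseudo-ablation; pooling
six replicate samples (~70 adjacent cells, comparable to a per-genotype mock
cell count in a real campaign) puts the expected mean angle at the analytic
45° uniform baseline with ~3° standard error.

The circumferential ground truth at a cell is the tangent of the ablation
distance-transform level line at the cell centroid — the same geometry the
proxy draws — so cross-module tests are self-consistent.

What the generator does **not** emulate: growth and drift between frames
(frames are pre-aligned, so reference runs disable registration with
`n_register=1`), cell divisions, curved 3D tissue (except in the dedicated
surface-volume fixtures, which embed the 2D images under a flat or dome
profile), realistic microtubule texture (bundling, branching, cytoplasmic
background), and puzzle-shaped cell geometry.  Passing the synthetic
end-to-end tests therefore demonstrates the correctness of the measurement
chain, not robustness to every property of real micrographs.

## Problem sizes used by the test suite and acceptance script

Orientation and geometry checks run on 64–256 px fixtures; the end-to-end
runs use one default-scenario ablation sample (12 adjacent cells × 13
timepoints on a 497² canvas) and six mock samples, which together complete
in well under a minute; bootstrap calibration uses 500 simulated datasets of
50 values.  These sizes give Monte-Carlo errors comfortably below the
asserted tolerances.

## Known limitations

- One segmentation for the whole series: unsuitable for fast growth,
  large deformation, or divisions.
- 2D projection: no true 3D orientation analysis (which would itself be
  biased by the anisotropic point-spread function); oblique-flank signal is
  only mitigated, not corrected.
- The proxy presumes wound-dominated, roughly circumferential stress; very
  elongated ablations, strong pre-existing stress patterns, or deeply
  concave (puzzle-cell) wound outlines weaken its meaning even with the
  convex-hull option.
- Anisotropy is sensitive to image quality and cytoplasmic background; the
  reporter line itself influences it, so cross-line comparisons of
  anisotropy need care.
- Replicating the original study's printed group statistics requires its
  deposited per-cell table, which is not redistributable with the package;
  the statistics stage consumes any tidy table with the documented schema
  (see `tests/test_acceptance.py` for the expected path).
- ImageJ ROI-zip export is not implemented; masks are exported as TIFF
  stacks.
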