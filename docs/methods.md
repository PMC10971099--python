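# Methods

This note documents the models, conventions and numerical choices behind
`lamescan`, and what the synthetic benchmark does and does not establish
about real farm data.

## Acquisition model and units

The sensor is modelled as an overhead time-of-flight camera at height
`H` (default 3.0 m) over a flat floor, emitting 132 × 176 rasters of
camera-to-surface distance. All distances and heights are metres
throughout; the CSV reader never rescales. Zero-distance dropout pixels
are preserved at read time so that I/O is lossless; downstream stages
treat them like any other value (a dropout inside a cow mask becomes a
spuriously large "height" only if it survives the mask, which the
detectors' height thresholding prevents in practice).

CSV rows flatten the raster row-major (all 176 columns of raster row 0,
then row 1, …). The row-major choice is the conventional raster order;
the simulator and the reader share it, so the convention is internally
consistent and round-trips exactly.

## Detection and the pixel-sum filter

The deployed system's neural instance detector is deliberately out of
scope: detection is a pluggable interface (frame → binary masks), with
two implementations. The reference detector thresholds height above the
floor (`H − depth > fg_delta`, default 0.3 m — above sensor noise, below
any standing animal's ridge) and takes 8-connected components of at
least 50 px (both defaults are exposed; the area floor suppresses
speckle). `MaskDirectoryDetector` ingests externally produced mask
rasters so a trained model's output can drive the same downstream chain.

The noise filter sums the masked **raw depth** values of each region and
keeps it only when the sum strictly exceeds 4000 metre·pixels. With
metre-scale depths (≈1.6–3.0 under this geometry) a cow footprint of
several thousand pixels sums to well over 4000 while a human footprint
of ~100–200 px sums to a few hundred. Users with sensors reporting other
units (e.g. millimetres) must rescale the threshold accordingly; it is a
config key everywhere it appears.

## Tracking

Greedy descending-IOU association at threshold 0.5 (the conventional MOT
default; at ≤ 25 px/frame displacement a cow's inter-frame IOU stays far
above it). Ties break by lower track ID, then leftmost detection, so
assignment is fully deterministic; optimal (Hungarian) assignment is
available behind a flag. A matched track's current box becomes the
matched detection's box — no motion model, matching the single-corridor,
always-visible setting. Track patience defaults to 1 frame: one miss
closes the track, because in this setting a visible cow is detected
every frame and a miss means the animal left the field of view. Both the
IOU threshold and patience are config keys since neither is dictated by
the physics.

## Backbone features

Feature extraction uses only frames whose bounding box spans the full
176 columns — the cow fills the corridor axis, so every column of the
profile is informative and all feature vectors share one length.

The height transform is `h = d − depth` inside the mask, clamped below
at zero (a pixel below the floor reference is sensor noise, and the
column maximum is otherwise noise-sensitive), and exactly zero outside
the mask. The reference distance `d` defaults to 2.8 m — the sensor's
calibrated floor reference — even though the camera is mounted at 3.0 m;
the 0.2 m offset is a property of the deployment's calibration, not of
the mathematics, so `d` is an exposed parameter and all synthetic-data
work sets `d = H` so that heights are exact.

Smoothing is a 2-D Gaussian with σ = 1.0 px and kernel radius ⌈3σ⌉ by
default, reflective borders, applied to the masked height field (the
mask boundary therefore bleeds slightly into the background zeros; the
column maximum is unaffected because it is attained on the body ridge).
The backbone profile is the per-column maximum over all 132 rows,
background zeros included — in-body columns report the dorsal ridge,
out-of-body columns report 0.

## Classification

Per-frame profiles feed Random Forest (100 trees), KNN (k = 5) and a
Decision Tree (unlimited depth) — hyperparameters are not dictated by
the method, so the defaults are the common ones, overridable per call
and recorded in every report. The transparent baseline predicts lame iff
the profile maximum falls below 1.2 m. Accuracy is reported per frame;
per-cow majority voting is an optional layer (ties go to lame, erring
toward flagging an animal for inspection). Train/test splits are always
by cow, never by frame: frames of one animal are strongly correlated and
a frame-level split would leak identity into the test set.

## Evaluation

Detection accuracy is `100·(TP+TN)/(TP+FP+TN+FN)`; tracking accuracy is
CLEAR-MOT `MOTA = 100·(1 − (FN+FP+IDS)/GT)`. Reported percentages round
half-up to two decimals. Session averages are **unweighted means of the
per-session percentages**, not pooled counts — the convention under
which the bundled reference tables' printed averages reproduce from
their rows. `score_run` matches predictions to ground-truth cow boxes
greedily by descending IOU at 0.5 (the standard detection-matching
convention); an identity switch is counted whenever a ground-truth cow's
matched track ID differs from its previously matched one; a rejected
region overlapping no ground-truth cow counts as a true negative
(correctly suppressed noise — the only well-defined negative in a
detection-only setting).

One bundled detection row (4 Sept PM: TP=1836, TN=1, FP=4, FN=0) prints
99.95 % but recomputes to 99.78 %; a TN/FP transposition would explain
the printed value. The tables keep both numbers and the recomputation
API flags the mismatch rather than correcting it. The six-session
detection average of 99.94 % likewise reproduces only from the printed
per-session values.

## The synthetic herd

The simulator exists to make every stage testable with exact ground
truth, and its geometry is chosen so the feature extractor's oracle is
*analytic*, not merely plausible:

- A cow is a separable surface `height(r, c) = dorsal(c)·cross(r)`.
  `cross` is an elliptical dome whose centre sample is exactly 1, so the
  per-column maximum of a rendered cow equals its dorsal curve to
  machine precision — the end-to-end oracle for the feature chain.
- `dorsal` is a tapered plateau (sine ramps over 15 % of the body at
  nose and tail) times an arch depression (a `sin²` bump that lowers the
  mid-body by up to 25 % at arch = 1), renormalised so its maximum
  equals the template's peak height exactly. Lame templates peak below
  1.2 m, sound templates above — the generator's labelling convention.
- Bodies are 240 px long × 57 px wide by default, moving at 8 px/frame
  along the corridor. The body exceeding the 176-column frame is what
  produces full-width bounding boxes mid-traversal; the pixel pitch is a
  simulator constant, not a sensor datum.
- An object is rendered and ground-truthed only while ≥ 56 of its body
  columns are in view (`min_visible_cols`), the same visibility gating
  MOT benchmarks apply to ground truth. This keeps every ground-truth
  footprint above the detector's minimum area and the 4000 pixel-sum
  threshold, so detector and ground truth agree frame-by-frame by
  construction rather than by tuning.
- Humans are 1.7 m-tall domes with a 13 × 9 px footprint: taller than
  any cow but with a pixel sum of a few hundred — always rejected by the
  filter, always detected before it.
- Sensor noise is i.i.d. Gaussian per pixel (SD a config key; 0.005 m in
  tracking fixtures, 0.01 m in the classification benchmark — the
  centimetre scale typical of time-of-flight sensors indoors). One
  seeded generator drives all stochastic draws, so a scene config
  reproduces bit-for-bit.
- Concurrently visible cows must keep a background gap between lanes;
  overlapping concurrent lanes are a configuration error because the
  tracker's no-occlusion assumption would be silently violated.

The benchmark suite (`make_benchmark_suite`) draws lame dorsal peaks
from U(0.95, 1.05) m with pronounced arches and sound peaks from
U(1.35, 1.45) m with near-straight backs — ±0.15 m margins around the
1.2 m boundary — in single-cow scenes of 24 frames, split 75/25 by cow
within each class.

**What passing tests show, and what they do not.** The synthetic herd
establishes that the implementation is correct: exact feature recovery,
zero tracking errors without occlusion, perfect class recovery at a
0.3 m margin. It does not emulate uneven floors, cows pausing or
overlapping, udder/head structures that perturb the dorsal line, sensor
dropout patterns, or the borderline locomotion scores that make real
herds hard — real-data accuracies will be materially lower than the
synthetic ones, and the synthetic results place no bound on them.

## Feature-oracle tolerance

The oracle tests compare extracted profiles to the analytic dorsal curve
at σ = 0.1 px (a near-delta kernel: the neighbour weight is
exp(−50) ≈ 2·10⁻²²), isolating the transform/masking/column-max chain
from smoothing bias. At the default σ = 1.0 the Gaussian lowers the
profile by ≈ ½σ²·(curvature) — up to ~10⁻³ m in the nose-taper region —
which is physically desirable smoothing, not error, and is why the
default-σ pipeline is tested against class-level behaviour rather than
the raw curve.

## Problem sizes

Test fixtures use single-cow scenes of 24 frames, a five-cow 200-frame
tracking scene, and a 76-cow benchmark herd (45 sound / 31 lame,
matching the reference deployment's class balance); these sizes keep the
whole suite under ~10 s while leaving every margin (pixel sums, IOU,
class separation) an order of magnitude from its threshold.
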