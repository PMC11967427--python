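# Methods

This note records the models, conventions and design choices behind
`sampdetect`, in the order data flows through the system.

## Image and scene model (simulate)

The simulator emulates what a fluorescence stereomicroscope records while a
Nile-Red-stained particle suspension is pumped through a shallow flow cell:
bright particles on a dark background, advected across the field of view,
with a peristaltic pump that is deliberately run intermittently so that
particles do not streak during exposure.

**Advection.** Each particle moves along +x with displacement
`v · p(t)` px/frame, where `p(t)` is a rectangular pulsation profile: the
particle moves during the duty fraction of each pump period and holds
position otherwise. This is the simplest profile consistent with an
intermittent pump actuator; no hydrodynamics is modelled. The default is
8 px/frame — the simulator is parameterised directly in px/frame because no
computation in the pipeline needs the physical mL/min to px/frame
conversion. Optional per-particle velocity jitter (default 0) models the
irregular motion of irregularly shaped particles; it is what makes
touching-then-separating events possible, and those events are logged, not
prevented: merged touching particles are a known undercount mode that the
evaluation quantifies.

**Intensity.** Frames are single-channel 8-bit (the detector operates on
one fluorescence emission band). A particle carries a per-particle
brightness drawn from [130, 230] and a smooth multiplicative
intra-particle field `1 ± a` (default a = 0.3) modelling uneven staining —
the documented failure mode in which an unevenly stained grain reads as a
fiber. Sprites are composited by maximum, blurred by a fixed Gaussian PSF
(σ = 0.8 px; no optical physics beyond this), and offset by Gaussian
background noise. Distractors (dim non-plastic objects) render at ≤30 % of
the particle brightness floor, so their edge gradients stay below a
correctly set hysteresis threshold.

**Grain shapes.** Grains are star-convex radial-harmonic polygons
`r(θ) = R (1 + s Σₖ aₖ cos(kθ + φₖ))`, k = 2…9, with amplitudes
`~ U(0.4,1)/k^0.6`. The family needs the higher harmonics: with fewer,
faster-decaying terms the reachable circularity floor at aspect 1 is ~0.55,
above much of the natural-sediment population. For given targets, the
amplitude scale `s` is bisected against polygon circularity (monotone), the
axis stretch against measured aspect, and both are then corrected against
measurements of the *rasterised* mask, because rasterisation systematically
inflates the perimeter (lowering circularity) and the hull aspect.
Acceptance is by rejection sampling: measured max feret within 15 % of the
target size, circularity within ±0.15, aspect within ±0.5. Below ~8 px
across these tolerances widen proportionally — at that scale rasterisation
quantises shape more coarsely than the nominal bands, and a failure after
bounded retries raises an error reporting the closest achieved values.

**Size distribution.** Grain sizes follow a lognormal moment-matched to the
configured mean/sd and truncated to [2 px · scale, 500 µm]: positive
support and right skew match observed sediment size distributions. The
size of a sampled grain is drawn once and kept across shape redraws so
shape infeasibility cannot skew the size distribution.

**Populations.** Two presets matter: the natural-sediment population
(152.9 ± 94.1 µm, circularity 0.42 ± 0.20, aspect 3.16 ± 1.51) is the
`SceneConfig` default; the pooled ground-polymer population
(300.3 ± 138.9 µm, circularity 0.60 ± 0.14, aspect 2.27 ± 1.13) is the
`artificial_mp()` preset and the default for classifier crop datasets,
because the shape-classification experiments use ground virgin polymer
particles as grain data. Fibers model clothing-derived microfibers: thin
strokes 1–2 px (18–36 µm) wide, 350–1200 µm long, with gentle curvature
(peak deviation ≤ 0.15 of length). Stronger curvature is supported by
`make_fiber_mask` but is not sampled by default: beyond ~0.15 the convex
hull of the stroke fattens until its caliper aspect falls below the
elongation gate that separates fibers from grains at all.

**Calibration and its resolution limit.** Generating ≥200 grains from the
natural-sediment parameters and measuring them back recovers mean size
within ±10 % and mean circularity within ±0.1 — *measured at 6 µm/px*. At
the flow-video scale of 18 µm/px a 150 µm grain spans ~8 px and
rasterisation erases the concave detail that low circularity requires (the
empirical raster floor is ~0.5 at that size and aspect), so small particles
genuinely read rounder at acquisition resolution; the reference shape
statistics themselves come from still-image measurements at finer
sampling. Consequently, passing the calibration test demonstrates that the
generator's *shape family* is correctly calibrated, not that an 18 µm/px
video preserves sub-pixel morphology — it does not, for the simulator and
for the real instrument alike.

**Determinism.** A `SceneConfig` (seed included) fully determines frames
and ground truth, bit for bit. The ground-truth log stores the ideal float
trajectory (so pure advection is exact for any velocity) alongside the
integer render offsets actually used for compositing; truth-side window
gating uses the rendered centroid.

## Detection (detect)

The cascade is the classic four-stage Canny pipeline, implemented stage by
stage: 5×5 binomial Gaussian, Sobel gradients, non-maximum suppression with
the gradient direction quantised to four sectors, hysteresis with strong
and weak thresholds. Thresholds default to frame-relative values
(high = 0.25 × max gradient, low = 0.4 × high) and can be set absolutely in
the run config — on real data one fixes staining concentration and exposure
and then sets an absolute threshold once. A constant frame has zero maximum
gradient and yields no edges.

NMS leaves one-pixel breaks in edge rings where the quantised direction
flips sector; a 3×3 morphological closing (configurable, `close_gaps_px`)
bridges them so that hole-filling recovers solid regions. Filling is
important for a second reason: unevenly stained particles have dark cores
that would otherwise split one particle into fragments. Regions are
8-connected; candidates below `min_area_px` (default 1 — the lower limit of
detection is a single pixel, 18 µm) are dropped, and only candidates whose
centroid lies in the half-open detection window are kept. RGB input is
reduced to the green channel by default (the Nile Red emission band),
with a luminance fallback flag.

Edge-based segmentation on PSF-blurred imagery lands on the blurred rim, so
detected regions measure ~1–2 px larger than the underlying mask; reported
sizes inherit that bias, which is a property of the method, not a defect of
the implementation.

## Linking and counting (track)

Matching is greedy nearest-neighbour against the flow-predicted position
(previous centroid + expected per-frame displacement), gated by maximum
link distance, maximum lateral |dy|, and a symmetric bound on the
frame-to-frame feret ratio. A candidate at the *unmoved* position is
accepted too (pump pause). Ties break deterministically (smaller distance,
then smaller x, then y), making the matching invariant to candidate
ordering. Greedy is adequate at the particle densities in play; the tests
check it against ground-truth trajectories. No Kalman filtering or
multi-hypothesis tracking.

Unmatched tracks age by one gap frame and retire after `max_gap_frames`
(default 2, which bridges short detection dropouts). A track is counted
once, when it terminates — at that point all frames are available, so the
representative (largest-area, i.e. best-focused and most fully stained
member; earliest frame on ties) supplies every reported measurement and the
crop.

## Morphometry (measure)

Boundaries are traced at iso-level 0.5 on the padded mask (marching
squares), so a w-px-wide object measures w, a single pixel has
feret_max 1.0 (= 18 µm at the default scale), and the perimeter is a
polygon length rather than a pixel-edge count — keeping circularity near
its continuum value. Max feret is the maximum pairwise hull-vertex
distance; min feret is the minimum width perpendicular to a hull edge; a
collinear boundary reports feret_min = 1 px by convention. Circularity can
slightly exceed 1 for small compact masks (discretisation slack ≲ 0.1 for
shapes ≥ 10 px across).

Size categories partition (0, ∞) with half-open bins; boundary values go to
the larger category, and sizes are rounded to the nearest integer pixel
before categorisation (whether the original system rounded down or to
nearest is unstated; nearest was adopted). The µm boundaries
(108/180/360 µm) are the pixel boundaries times the scale and the px and µm
categorisations agree exactly for integer pixel sizes.

## Classification (classify)

The rough rule calls fiber when aspect ≥ 4, or aspect ≥ 3 with
circularity < 0.2. The gate sits above the natural-grain mean aspect of
3.16 — natural grains are themselves elongated, which is exactly why a rule
alone is not enough and a trained classifier follows.

The CNN is three 3×3 conv blocks (8/16/32 channels, each ReLU + 2×2
max-pool) and a 64-unit dense head, written in plain numpy (im2col
convolutions, Adam), so training is deterministic under a fixed seed and
the backprop is verified against numerical gradients in the test suite.
Crops are min–max normalised per crop — staining brightness varies per
particle and must carry no class information — and resampled to 48×48 (at
32×32 the 1–2 px fiber width blurs away and elongated grains become
confusable). Training uses balanced classes, 250 crops per class expanded
×8 by mirror and 90° rotations, batch 32, lr 1e-3, at most 200 epochs with
early stop once the mean training cross-entropy drops below 0.005 (the
learning converges to a small residual error; misclassification rate alone
stops too early, leaving under-confident probabilities) and a minimum of
5 epochs (with 8-fold augmentation the loss target can be crossed before
held-out probability margins harden). Confidence is the
predicted-class probability ×100 (≥ 50 for a binary argmax). Oversized
particles are downscaled into the 100×100 crop preserving aspect. Models
serialise to `.npz` with their training metadata and reload with
bit-identical predictions.

The human relabelling step used when preparing real training data is
replaced by simulator ground-truth labels; for real data a relabel CSV can
override labels before training.

## Evaluation (evaluate)

The confusion summary follows the reference protocol: an answer is correct
only if the label matches *and* confidence ≥ 90 %; the plain
label-agreement rate is reported alongside because the published table does
not say which rule produced it (the single published error is the same
particle either way). Detection efficiency matches counted records to
ground-truth trajectories one-to-one (greedy by distance, gate 12 px) and
reports unmatched records as false positives, never as efficiency; merged
touching pairs are tallied from the ground-truth touching log. Throughput
(particles/min) is informational only — it depends on hardware and frame
rate and is never asserted.

## Problem sizes used in the tests

The bundled validation runs at deliberately modest scale: scenes of
480×360 px and ~100 frames with ~9 particles for counting conservation;
200 grains for population calibration; 275 crops per class (250 train,
25 held out) for the classifier reproduction, which trains in a few minutes
on one CPU. These sizes were chosen so the whole suite is convenient to run
routinely; the pipeline itself streams frames and has no scale-specific
assumptions.

## What passing the tests does and does not show

The simulator provides exact ground truth, controlled noise, and particles
that always fluoresce. Real flow-cell video adds what the simulator leaves
out: autofluorescent organic debris, focus drift, bubbles, particles
entering half out of plane, pump-speed variation correlated across
particles, and staining failure. Passing the synthetic benchmarks therefore
validates the *algorithmic* contracts — each particle counted once, sizes
measured to the stated conventions, the classifier separable on shape —
not field performance on any particular sample. Polymer-type
identification is out of scope entirely: Nile Red fluorescence does not
encode polymer identity.
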