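# Methods

This note documents the models and procedures `roboyield` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Optics

The fisheye lens is modelled as equidistant with a radial polynomial: a ray
at angle θ from the optical axis lands at radius `f·θ_d` with
`θ_d = θ(1 + k₁θ² + k₂θ⁴ + k₃θ⁶ + k₄θ⁸)`, versus `f·tan θ` for a pinhole.
This is the standard fisheye calibration model. Defaults are the calibrated
side-camera intrinsics, f = (410, 410) px and principal point (383, 526) px
at native 1920 × 1080; the distortion coefficients are not part of that
calibration record, so the simulator defaults to k = (−0.05, 0.01, 0, 0),
chosen to give clearly visible but cleanly invertible barrel curvature.
Inversion solves θ from θ_d with 10 Newton iterations (ample in the small-|k|
regime; the point round trip closes to ~1e-13 px). Image warps resample
bilinearly; coordinates are 0-based, x right, y down, points at pixel
centers, and odd crop margins shift toward the top-left for determinism.
After undistortion, a central 1000 × 1000 window is cropped (no resampling)
to discard the blurry frame margins.

## Frame assignment and splitter sampling

Plot intervals are half-open `[start, stop)`: a frame at a plot's exact stop
time belongs to the next interval or the alleyway, never to the closing plot.
Splitters are placed on the time axis — a proxy for distance at constant
robot speed, and the only axis the frame data carries; under wheel slippage
this is approximate, which is the main caveat of the scheme. Each row-side
sequence's span is divided into eight sections by seven splitters at
fractions i/8 (i = 1..7); splitters 1 and 7 sit too close to the plot edges
and are dropped, the frame nearest each of splitters 2–6 is selected (ties to
the earlier frame), and a side's two rows are concatenated: 10 images per
side, 20 per plot. Sequences shorter than 8 frames mark the plot degenerate;
it is excluded with a warning rather than padded.

## Counting model

A point-proposal crowd-counting network. The backbone is a configurable
stack of 3 × 3 conv + ReLU blocks with 2 × 2 max-pooling in the first
log₂(stride) blocks (default 4 blocks, stride 8, 8/16/32/32 channels). The
head places √K × √K reference points per feature cell (K = 4) and predicts,
per reference point, a pixel offset (scaled by the stride) and a confidence
logit. Training matches proposals to ground-truth points one-to-one with the
Hungarian algorithm on cost = Euclidean distance − λ·score (λ = 1), then
minimises a weighted binary cross-entropy (positive weight 8, countering the
~16:256 positive:proposal imbalance; without it the score head collapses to
"no seeds" for many epochs) plus 0.02 × the mean squared matched-offset
distance. Matching is treated as a constant within a step, so the head
gradients are analytic. Inference keeps proposals with score ≥ 0.5 and
merges survivors greedily by descending score through a k-d tree, suppressing
any point strictly within the merge radius of a kept one (default 8 px at the
1000-px working scale; 4 px in the 64-px test scenes). Adam is the optimizer
(lr 1e-4 default; the desk-scale experiments use 1e-3), and the best
checkpoint by validation MAE is restored. Count metrics are MSE, MAE, MAPE
(percent, zero-truth images excluded with a warning) and the R² of the
least-squares line of predicted on true counts.

Dataset combinations are named (`ISU_NO_AUG`, `MIX_NO_AUG`, `ISU_AUG`,
`MIX_AUG`) over three components: a base annotated set, its sensor-effect
augmented copy, and an external set from a different camera/site.

## Sensor-effect augmentation

Each original image gets exactly one augmented variant. Effects compose as
blur → chromatic aberration → exposure → noise (noise last, as in a physical
sensor chain; the composition order is otherwise unconstrained). Chromatic
aberration shifts the red and blue planes by ±s px laterally with green as
the geometric reference, so point annotations are untouched by all four
effects. Noise is additive Gaussian. Intensities are drawn per image from
configured ranges (defaults: sd ∈ [0, 0.06], σ ∈ [0, 1.5] px, shift ∈
[0, 1.5] px, gain ∈ [0.7, 1.3] on [0, 1] images) — visible corruption that
leaves scenes countable; the upstream randomiser this emulates does not
publish its distributions, so the ranges are config, and every draw is logged
per image.

## Yield regression

The counting backbone is frozen (asserted bit-identical before/after
training) and used as a feature extractor on a plot's 20 sampled images. The
10 maps of a side are summed elementwise — making the prediction invariant to
frame order within a side — and the two side-sums are concatenated along
channels, side A first (channel concat preserves spatial registration; the
axis is otherwise a free choice). The regressor is conv(3 × 3, 64ch default)
→ ReLU → 2 × 2 max-pool → flatten → fc 256 → 64 → 1, trained with Adam on
elementwise MSE, batch 8, 50 epochs. Targets are z-scored during training and
the transform inverted at prediction, which stabilises MSE across yield
scales; widths are config since the reference design does not fix them.

## Moving-grid spatial adjustment

The neighbourhood is the 5 × 5 window minus the four corners and the center
(20 cells, symmetric under quarter turns). Each plot's moving mean x_i
averages the in-bounds, non-missing masked neighbours (edge plots simply use
fewer cells); b is the OLS slope (with intercept) of the observed phenotype
on x_i; and `p_adj = p_obs − b(x_i − x̄)` with x̄ the mean of the x_i — which
makes the adjustment preserve the grand mean exactly. Zero variance in x_i
yields b = 0 with a warning. Adjustment is applied once (not iterated), and
replicate averaging is left to the caller after adjustment.

Yield normalisation converts combine mass to MT/ha at 13 % moisture by
dry-matter proportionality — mass × (100 − m)/87, then per-hectare scaling —
the standard grain-trade correction; only the 13 % target is fixed upstream.

## Selection-threshold ranking

For a threshold q, the top set is the ⌈qN⌉ largest values of each vector
independently, ties broken by stable plot order (and logged implicitly by
that rule — with N = 650 and q = 0.2, ⌈qN⌉ = 130, so off-by-one FP/FN counts
in source material indicate a different tie convention there). Counts follow
the breeding definitions: TP = true top entries kept, FP = poor entries kept,
FN = top entries missed, TN = poor entries dropped; accuracy = (TP+TN)/N,
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); zero denominators give
NaN with a warning, never a silent 0. Equal-size top sets force FP = FN.
NaN phenotypes are excluded pairwise.

## Synthetic generator

Scenes are shaded ellipses ("seeds", pale, eccentricity-jittered) over
multi-octave smoothed-noise texture, with dim blurred background-plot seeds
that are rendered but never annotated, and dark foliage ellipses as
occluders. A seed is annotated iff ≥ 50 % of its own pixels are on top and
unoccluded at the end of drawing — a testable version of "clearly discernible
to a rater". Foreground seeds keep a minimum center separation of 1.4 × the
maximum radius so mutual overdraw cannot cross the visibility threshold;
infeasible placements raise a `PlacementError`. Fields draw
`true_yield = genotype_effect + trend(range, pass) + N(0, noise_sd)` (clipped
at a small positive floor with a warning) and
`true_seed_count = round(true_yield × seeds_per_MT)`; the default trend is a
separable linear slope plus one Gaussian bump, exercising both the global
regression slope and the local moving means. Collections emit, per plot, four
sequences (rows 1–2 × sides A–B) of evenly spaced timestamps inside the
plot's interval (constant speed: interval = plot length 2.13 m / speed
1 m/s; speed is config since the survey speed is not pinned down, only a
4 kph capability), with forward fisheye distortion applied to frames and
truth points.

What it does *not* emulate: photorealistic pods/foliage, lodging, disease,
weather or illumination fields, variable robot speed, camera shake, or
inter-rater annotation noise. Passing tests therefore show the pipeline's
machinery is correct and that its qualitative orderings (augmentation helps
under sensor shift; fused features carry yield signal; adjustment removes
spatial trend) hold under controlled conditions — not that real-field
accuracies are reproduced.

## Desk-scale experiment sizes

The test experiments run on 64 × 64 working crops with a 6-channel,
merge-radius-4 counter: the augmentation-ordering experiment trains on 200
images (plus 200 augmented) for 8 epochs across 3 seeds and evaluates on a
50-image sensor-corrupted set; the yield-recovery experiment trains the
regressor on 100 plots and evaluates on 100 held-out plots (20 images each)
across 3 seeds against an R² floor of 0.3; the spatial-adjustment experiment
uses a 20 × 20 field over 5 seeds. At this scale `seeds_per_MT = 60` keeps
per-image densities (3–15 visible seeds) comparable to the annotated-scene
corpus; the 1000-px-scale default is 300.

## Known limitations

- The numpy CNN is stride-1-conv/2×2-pool only and CPU-bound; it is sized
  for the synthetic working crops, not for 1000 × 1000 field imagery.
- Splitter positions in time assume constant speed within a plot.
- The equidistant model omits tangential distortion; intrinsics must come
  from an external calibration.
- Greedy score-ordered merging is order-dependent near ties; ties are broken
  deterministically by index.
- Absolute counting/yield errors on real imagery are out of reach of the
  synthetic scenes by construction; only ordering/recovery properties are
  claimed.
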