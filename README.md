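# roboyield

Seed counting and plot-yield estimation for soybean breeding trials from
ground-robot fisheye video, with a synthetic field generator so the whole
pipeline runs and is tested at desk scale.

## The problem

Plot combines are the standard way to measure yield in a breeding program,
and they are slow, expensive and failure-prone. An alternative is to drive a
small ground robot with side-facing fisheye cameras between the rows at full
maturity (stage R8), detect the seeds visible in the video frames, and use
seed counts — or features correlated with them — to *rank* genotypes for
selection. Ranking, not absolute yield, is what a breeder needs to discard
poor performers.

`roboyield` implements that pipeline end to end:

1. **Optics** — frames are modelled with an equidistant fisheye lens
   (`theta_d = theta (1 + k1 θ² + k2 θ⁴ + k3 θ⁶ + k4 θ⁸)`, default
   intrinsics f = (410, 410) px, principal point (383, 526) px at
   1920 × 1080), undistorted, and center-cropped to a 1000 × 1000 working
   window.
2. **Plot frames** — frames are assigned to plots via a plot-interval CSV
   (half-open `[start, stop)` intervals), organised by row (1/2) and side
   (A/B), and subsampled by the splitter scheme: each row-side's time span is
   split into 8 sections by 7 splitters, the middle 5 are kept and the
   nearest frame to each is selected — 10 images per side, 20 per plot.
3. **Counting** — a point-proposal (P2PNet-family) counter: a small conv
   backbone (stride 8) plus a head predicting per-reference-point offsets and
   confidences, trained with one-to-one Hungarian matching (cost = distance −
   λ·score), weighted cross-entropy and an offset L2 term; inference
   thresholds scores and merges near-duplicates greedily via a k-d tree.
   Sensor-effect augmentation (noise, blur, chromatic aberration, exposure)
   is available to harden the counter against camera/lighting shift.
4. **Yield regression** — the counter's backbone is frozen; the 10 feature
   maps per side are summed, the two side-sums channel-concatenated, and a
   small conv + pool + 3-layer MLP regresses plot yield in MT/ha (Adam, MSE,
   batch 8, 50 epochs).
5. **Field statistics** — moving-grid spatial adjustment
   `p_adj = p_obs − b (x_i − x̄)` with a 5 × 5 neighbourhood minus corners and
   center (20 cells), moisture normalisation to 13 % (MT/ha), and
   selection-threshold ranking metrics (accuracy, sensitivity, specificity at
   top-10/20/30 % cutoffs).
6. **Synthetic field** — generates everything the field would: scenes of
   shaded-ellipse "seeds" over textured backgrounds with exact point ground
   truth (a seed is annotated iff ≥ 50 % of its pixels are visible;
   background-plot seeds are rendered but never annotated), fisheye
   collections with timestamps and interval CSVs, and layouts with genotype
   effects plus a smooth spatial trend.

The neural parts run on a compact numpy CNN with manual backprop
(`roboyield._net`), sized for the small working crops the tests use.

## Worked example

```bash
roboyield run-all --out demo --seed 3 --ranges 5 --passes 5 \
    --image-size 32 --count-epochs 1 --yield-epochs 5
```

simulates a 5 × 5 field, trains a toy counter and yield regressor, spatially
adjusts true and estimated yields, and prints the ranking report, e.g.:

```json
{
  "10%": {"TP": 0, "TN": 19, "FP": 3, "FN": 3,
          "accuracy": 0.76, "sensitivity": 0.0, "specificity": 0.8636},
  "20%": {"TP": 0, "TN": 15, "FP": 5, "FN": 5,
          "accuracy": 0.6, "sensitivity": 0.0, "specificity": 0.75},
  "30%": {"TP": 4, "TN": 13, "FP": 4, "FN": 4,
          "accuracy": 0.68, "sensitivity": 0.5, "specificity": 0.7647}
}
```

Each block gives the confusion counts and selection metrics for retaining the
top fraction of plots by *estimated* adjusted yield against the top fraction
by *true* adjusted yield: `TP` plots correctly kept, `FP` poor plots wrongly
kept, `FN` good plots missed, `TN` poor plots correctly dropped. (At this
deliberately tiny demo scale the estimates are noisy; the test suite runs the
properly sized experiments.) The run directory also contains `layout.csv`,
`predictions.csv`, training logs and a `manifest.json` recording the config
hash and all derived stage seeds.

Library use mirrors the CLI; see the module docstrings under `src/roboyield/`
and `docs/methods.md` for the model details and design choices.

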