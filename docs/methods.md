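# Methods

## The activity statistic

For successive frames I(t) and I(t+Δ) the pipeline computes the absolute
difference image, binarizes it with an adaptive local threshold, removes
isolated single pixels, and reports three numbers per pair:

* **A₀** — the white-pixel count, the classic frame-differencing motion
  index. It is proportional to the area of the symmetric difference of the
  animal's two footprints, so it grows roughly linearly with displacement
  up to one body length and is constant beyond.
* **D** — the mean Euclidean distance over all C(n, 2) unordered pairs of
  white-pixel centers (0 when n ≤ 1: a single changed pixel carries no
  extent information). Once the footprints separate, about half of all
  pairs straddle the two footprints, so D grows ≈ d/2 with displacement d.
* **A = A₀ · D** — the improved locomotion activity, which stays nearly
  proportional to the travel length over the whole range.

Distances are between pixel centers in pixel units; no physical calibration
is applied (activity is an arbitrary-unit index). Color input is collapsed
to intensity with the Rec. 601 luma weights.

## Adaptive threshold

The binarization rule is: pixel p is white iff

    diff(p) >= min_abs_diff  AND  diff(p) >= (threshold_percent/100) × max(window(p))

with the local maximum taken over an edge-replicated
`threshold_window × threshold_window` neighborhood. `threshold_percent`
defaults to 83. A pure ratio rule would mark flat noise white wherever the
window maximum is itself tiny (0.83 × 3 ≈ 2.5 admits nearly everything), so
the absolute floor `min_abs_diff` (default 10 on the 0–255 scale) suppresses
near-zero windows while leaving the ratio as the operative criterion on real
motion. The window default (15 px) is of the order of the blob scale;
both are configurable. The floor and the window are stated explicitly
because local-threshold dialects differ between implementations; this rule
is deterministic and is tested against a literal per-pixel oracle.

## Despeckling and box filter

Despeckling removes connected components of size exactly 1 (default
8-connectivity — the conservative choice that removes only truly isolated
pixels) and is idempotent. The optional pre-subtraction box filter is a
plain neighborhood mean (`box_kernel`, default 3, odd, edge-replicated);
it is off by default (larvae) and recommended for adult fish, where sensor
noise on the larger body otherwise inflates the mask.

## Cost control for the pairwise distance

All-pairs distance is O(n²) in the number of white pixels. Up to
`max_exact_pairs_pixels` (default 2000) the computation is exact; above it,
D is computed on a seeded uniform subsample of that size and the sample is
flagged approximate. The estimator is unbiased; its per-draw relative error
scales like 1/√(number of subsample pairs) (≈ 2 % on average when halving
200 pixels to 100). The subsample seed lives in the pipeline config, so
traces are reproducible bit-for-bit.

## Synthetic generator

The generator emulates the assay optics: a dark ellipse (default 40/255)
with its major axis along the direction of motion, on a light background
(220/255), moving prescribed per-step distances with either a fixed heading
or a random-walk heading (Gaussian turns, default SD 30°). The boundary is
anti-aliased by a signed-distance approximation, which makes every
downstream statistic a continuous function of sub-pixel position — needed
for clean regression against true displacement. Gaussian pixel noise of SD
`noise_sd` is added after rendering and clipped to the intensity range.
Default canvas 640×480 (capture resolution is rig-specific and
configurable).

The trajectory starts at the image center and reflects off an inset margin
so the blob never leaves the frame; ground truth records the *realized*
displacements, which equal the requested steps whenever no reflection
occurs. One RNG per sequence is consumed in a fixed order (trajectory, then
per-frame noise), so (spec, seed) determines the sequence bit-exactly.
Turns are applied only on steps of positive length: a stationary animal
neither advances nor re-orients, so a death trace renders identical frames
from the cessation index on (the pre-drawn turn stream keeps the RNG
consumption identical either way).

What the generator does *not* emulate: tail-beat kinematics and posture
change (real fish produce activity even when the centroid is still),
occlusion, refraction at the well rim, illumination drift, and multi-animal
wells. Passing validation on synthetic data therefore demonstrates the
geometric core of the metric — distance sensitivity and saturation behavior
— not robustness to every optical artifact of a live rig.

## Trace analyses

* **Binning**: half-open bins [k·w, (k+1)·w) anchored at t = 0; a bin mean
  is the arithmetic mean of the samples falling in it; empty bins are
  missing (NaN), never zero-imputed. Bin width is a required argument
  (5-min and 10-min bins are both in routine use; no silent default).
* **Heat maps**: one row per animal grouped by condition, one column per
  bin; rendered raw or per-animal peak-normalized (both offered since
  either convention is seen in practice).
* **Cessation (death proxy)**: the earliest time t\* such that every sample
  from t\* to the end is ≤ ε and the quiet tail lasts at least `hold`
  seconds. Defaults: ε = 0 for noise-free data, with an adaptive helper
  (5th percentile of the first 10 minutes) for noisy traces;
  hold = 600 s. These are explicit, overridable conventions.
* **Outlier exclusion**: the single animal with the largest sample variance
  of its raw activity series is dropped per condition (first-in-order on
  ties, documented); variance of binned means is available behind a flag.
* **Group comparison**: the statistical unit is the per-animal mean
  activity (avoids pseudo-replication across time bins); one-way ANOVA
  followed by Tukey HSD (Tukey–Kramer for unbalanced groups, via
  statsmodels), with the conventional star mapping (*, **, *** for
  adjusted p < 0.05, 0.01, 0.001). All-identical inputs short-circuit to
  F = 0, p = 1 rather than 0/0.
* **Curve fits**: OLS for the linear validation (R² = 1 − SSres/SStot;
  constant y is reported as slope 0, R² = 0 by convention), and
  Levenberg–Marquardt least squares for the three-parameter sigmoid
  y = a/(1 + e^(−(x−x₀)/b)) with starts a = max(y), x₀ = median(x),
  b = range(x)/4; non-convergence and degenerate (constant-y) inputs are
  flagged in the result, never silently returned.

## Validation experiments and problem sizes

`fishact.validation` packages the experiments the test suite and the
acceptance script run:

* **Displacement sweep** — 32 noise-free two-frame sequences, blob
  20×6 px, fixed heading, displacements spanning 0.25×–4× the blob length.
  D and A are regressed on true displacement (both nearly linear); A₀ is
  fitted by the sigmoid and its plateau is checked (< 5 % change from 1.5×
  to 4× blob length while A strictly increases).
* **Death detection** — 40-frame sequences with a random cessation index;
  activity first reads zero one capture interval after motion stops, so
  recovery within one interval is scored a success.
* **Group recovery** — 3 conditions × 5 animals, 25 frames each, per-step
  lengths drawn N(μ, 1 px) clipped at 0 with μ = 2/6/10 px on a 100×100
  canvas with a 12×4 blob. Per-animal mean activities go through the
  ANOVA/Tukey layer; the planted ordering of group means and the
  significance of the extreme pair are scored over 100 seeded replicates.
  These sizes keep the full suite around a minute while leaving the planted
  effects far above the noise floor.

## Known limitations

* The threshold rule is one defensible reading of "adaptive local
  thresholding at 83 %"; other dialects (local-mean + offset) would need a
  different floor. The rule is a pluggable function, so alternates can be
  swapped without touching callers.
* Rectangular well regions only; circular masks for spot-plate depressions
  are not implemented.
* No dose–response (EC₅₀) modeling, survival analysis, or behavioral
  classification; the sigmoid fit here is a validation tool, not a
  dose–response model.
* The cessation rule cannot distinguish death from sustained quiescence;
  in the assay this is resolved by inspection, and the `hold` parameter
  only controls how long a quiet tail must be before it is reported.
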