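# Methods

`wormspectra` implements a desk-scale, fully synthetic re-creation of a
behavioral-imaging toxicology workflow for *C. elegans*: single worms in
microwells are pre-exposed to ascorbic acid (0, 5, 10 mM), then exposed to
sodium nitrite (0, 1000, 3000, 6000, 10,000 mg/L) under three food regimes
(AA, PA, PP — absence/presence of *E. coli* food across the two 24-h
phases), filmed in 1-minute captures at 30 fps, and scored for mortality.
Because no raw videos or count tables are publicly deposited, every stage is
driven by a ground-truthed generator, and the package's claims are
parameter-recovery and direction-of-effect properties on that synthetic
material — not reproductions of any real-data figure.

## The synthetic worm

**Locomotion** is a two-state Markov chain. A worm in the *run* state enters
a *turn* with per-frame probability `turn_rate/fps` and leaves it with
probability `turn_exit_rate/fps` (defaults 0.20/s and 1.2/s, giving ~14%
turn-state occupancy at control, the regime of healthy swimming). Run frames
advance the centroid by `run_speed/fps` (default 40 px/s at ~80 px body
length) along a heading with Gaussian per-frame noise (sd 0.15 rad in runs,
1.0 rad in turns, so turns reorient); turn frames move at 20% of run speed.
Per-frame step lengths carry multiplicative gamma noise (mean 1, cv 0.5):
real swimming speed fluctuates, and this makes the above-motion-threshold
step fraction degrade smoothly with dose instead of cliff-dropping when the
mean step crosses the threshold. A Bernoulli draw on `activity_prob`
(default 0.95) decides whether the worm moves at all during a capture;
inactive worms emit a constant-position, constant-length track. Paths are
reflected into an arena sized so the rendered worm always fits the frame —
the folding preserves per-step displacement magnitudes, so summed
displacement is unaffected.

**Posture** is a circular arc of constant body arc length. Bend amplitude
`a ∈ [0,1]` maps to total arc angle `2πa`, so the chord/arc ratio — the
per-frame "% worm length" — is `sinc(a) = sin(πa)/(πa)`: 1 for a straight
worm, 2/π for a semicircle, 0 for a closed circle. The turn/run posture
boundary (chord = 50% of body length) sits at `a ≈ 0.6034`. Run-state bend
amplitude is 0.40 (chord ≈ 76%) and turn-state 0.90 (chord ≈ 11%), each with
Gaussian frame noise (sd 0.075) clipped into the state's side of the
boundary, so generated ground truth always satisfies the zone semantics
(turn < 50% ≤ run). The closed-form chord/arc map is what makes segmentation
testable against analytic geometry.

**Dose effects.** Each affected parameter is multiplied by
`1 − attenuation(asa) · food_scale(food) · slope · dose/10000`. Slopes
(turn rate 0.5, speed 0.5, activity 0.4, run/turn bend 0.25/0.2) encode the
reported qualitative effects: fewer and shallower turns, less movement,
less activity, straighter bodies. Ascorbic acid attenuates the whole nitrite
effect multiplicatively (1.0 / 0.45 / 0.33 at 0 / 5 / 10 mM, i.e. LC50
rises a bit over 2-fold at 5 mM and ~3-fold at 10 mM), and the food regime
scales the effective dose (AA 1.0, PP 0.76, PA 0.45, the ratios of the
treatment LC50s ~2900 : ~3800 : ~6500 mg/L). Using the *same* effective dose
in behavior and in the mortality model is deliberate: both blocks are then
functions of one latent exposure variable, which is exactly the structure
the PLS analysis is meant to detect.

**Mortality** is binomial with a two-parameter log-logistic (Hill)
dose-response `p(d) = 1/(1 + (LC50/d)^h)` (default h = 4, AA base LC50
2900 mg/L), with `p(LC50) = 0.5` by construction when the baseline is zero.
The Hill family was chosen over probit for its closed-form LC50 parameter
and stability at four dose levels.

**Rendering** draws the worm as a dark constant-arc-length ribbon on a
bright noisy field (defaults 60 on 200 ± 4 grayscale, 256×256 test frames;
the capture geometry of 1080×720 is available through `RenderConfig`). The
centerline has arc length `body_length − 2·half_width` and is stamped with
round caps, so a straight capsule's Feret extent equals the body length
exactly; for curved worms the caps add a small positive bias of order
`2·half_width·(1−fraction)/body_length` (≈ 0.015 at a semicircle with
default sizes, inside the 0.03 acceptance tolerance). Below a semicircular
bend the widest caliper of the blob is the arc's diameter rather than its
chord, so measured "length" saturates — a genuine property of Feret-based
length that the real assay shares; the turn/run boundary is unaffected
because the diameter of any super-semicircular arc of these worms is still
below half the body length.

## Measurement pipeline

**Segmentation** inverts each frame, thresholds (Otsu by default; fixed
override), labels 8-connected components, discards blobs under 15 px and
keeps the largest. Frames with no surviving blob, with insufficient
intensity range, or where the foreground would cover more than 25% of the
frame (a wormless noisy frame otherwise percolates into one giant
"component") are flagged `valid=false`, never raised. The worm's per-frame
length is the blob's **maximum Feret diameter**, computed on the convex hull
but equal to the brute-force pairwise maximum. Feret extent — not skeleton
arc length — is the right reading because it shrinks with body bend and
therefore carries the postural signal; a skeleton length would be
bend-invariant.

**Block A** locomotion descriptors per worm: `M` (sum of consecutive
valid-frame centroid steps of at least `motion_threshold` = 1 px, to
suppress segmentation jitter), `t` (number of such steps over fps — movement
time, not elapsed time), `V = M/t` (0 when t = 0), and `A_m`, the
axis-aligned bounding rectangle of visited centroids. The two 1-minute
captures of a worm are summed (`M`, `t`, `A_m` add; `V` is recomputed; a
bounding-box-union alternative for `A_m` is available in config). Per
treatment: means of `M, t, V, A_m` over worms, `ACT` (percent of worms with
`M` ≥ 5 px), `M/A_m` of the treatment means, and `M/ACT` = ΣM per active
worm (the "movement per active nematode" reading; zero when no worm moved).

**Block B**: per-frame lengths are normalized to the worm's maximum observed
length across both captures (removing worm-size variation without any
global calibration), clipped to [0, 100], and histogrammed into 100 bins
([i, i+1) half-open, [99, 100] closed) in % time — the postural spectrum,
which always sums to 100. Zones partition the axis at <50 (turns), [50, 85)
(runs) and ≥85 (M-runs); zone fractions are computed through the histogram
so they equal the corresponding spectrum sums bit-exactly. Two consequences
of the per-worm-max reference are worth knowing: an inactive worm's
constant-length track normalizes to a single bin at 100% (so rising
inactivity feeds the M-runs zone — directionally consistent with the
paralysis-like phenotype it stands in for), and the max statistic sits
~3.4 noise-sd above the mean run posture, which inflates control M-run
occupancy relative to an oracle that knew the true unbent length. Neither
affects the turn zone or any direction-of-effect property.

**LC50** is least-squares on the Hill curve, fitted in (log LC50, slope)
coordinates so the estimate is scale-equivariant in dose, with an
interpolation fallback (linear in % mortality vs log10 dose between the
bracketing doses) when the fit fails. Curves that never reach 50% mortality
return an explicit `gt_max_dose` censored outcome rather than a number —
at 10 mM ascorbic acid the PA series genuinely exceeds the tested range,
and the pipeline reports exactly that. Proportions are fitted unweighted by
default; binomial weighting is a flag.

**Multivariate.** Block A matrices are autoscaled (mixed units: px, s, px/s,
px², %); Block B spectra are mean-centered only (bins share units) — the
standard chemometrics conventions, stated here because the choice is ours.
PCA is the SVD of the preprocessed matrix with explained variance
`100·σᵢ²/Σσ²` and the dominant loading of each component forced positive.
PLS1 is classical NIPALS (w ∝ X'y, t = Xw, p = X't/t't, q = y't/t't,
deflation), default 2 latent variables, each LV's score sign fixed so its
covariance with y is positive; the calibration R² is evaluated on the
training rows, and LV1 loadings are exported per spectrum bin. scikit-learn
is never in the computation path; it appears only as an independent oracle
in the tests.

## The synthetic experiment and its problem sizes

The default `RunConfig` runs the full 45-cell factorial (3 ascorbic acid ×
5 nitrite × 3 food; the source protocol reports 30 treatments without
stating the factorization, so the generator enumerates a configurable grid
and the default keeps the complete factorial), with 6 behavior worms per
treatment (2 captures × 60 s × 30 fps each, as ground-truth tracks) and 60
lethality worms per treatment. Worm random streams are keyed by (seed, food,
worm, capture) and deliberately *not* by ascorbic acid or nitrite level, so
every cell sees the same virtual cohort and dose contrasts are paired —
common random numbers, the standard variance-reduction device for
simulation experiments. Rendering + segmentation of full videos is supported
(`use_video=True`) and validated on short clips; the default experiment
skips pixels because the tracker is tested separately against rendered
ground truth and the downstream statistics are identical on cached tracks.

One seed's experiment takes ~1 s on one core; the direction-of-effect suite
and the acceptance script aggregate seeds 1–10 (≈540 worms per dose level
marginally). The turn-occupancy Monte-Carlo cross-check uses 4,000 replicate
tracks of 15 s at 10 fps against an independently coded per-frame chain.

## Numerical choices and degenerate inputs

- All randomness flows through explicit integer seeds via
  `numpy.random.SeedSequence`; identical (config, seed) reruns are
  byte-identical, and CSV round-trips use `float_precision="round_trip"`.
- Zone boundaries are half-open exactly as defined (50 → run, 85 → M-run;
  100 falls in the closed last bin and the M-run zone).
- Bend noise is clipped 1e-6 inside the turn/run boundary on both sides so
  floating-point equality at the boundary cannot flip a ground-truth zone.
- Empty series, empty blobs, single-row matrices, zero-variance responses,
  mismatched fps and out-of-frame renders raise immediately with named
  errors; a frame without a detectable worm is a `valid=false` observation,
  not an exception. Constant responses in a tiny pipeline run yield R² = NaN
  with a warning instead of aborting the bundle.
- PLS deflation stops early if the residual carries no covariance with y
  (weight norm < 1e-12); the model then reports the LVs actually extracted.

## What passing tests do and do not show

The generator reproduces the *structure* the analysis assumes — monotone
dose effects, paired treatment cells, a mortality curve with a known LC50,
postural spectra whose mass moves from turns toward M-runs under nitrite and
back under ascorbic acid. Passing tests therefore show the pipeline
*recovers what the generator put in* (LC50 median |relative error| ~4% at
n = 60/dose; PLS R² ≈ 0.96 on the seed-averaged experiment). They do not
show that real videos are segmented as cleanly (no occlusions, debris,
lighting drift or multi-worm wells are simulated), that real postural
spectra are two-state (real worms have a continuum of bends and distinct
gaits), or that the real LC50s equal the synthetic defaults. Real-data
figure values are used only to set the study conditions, never as test
targets.
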