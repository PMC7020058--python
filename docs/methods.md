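# Methods

`bitekit` detects bites — the moments food enters the mouth — in pose-keypoint
streams extracted from videotaped meals, and derives the meal-microstructure
measures built on them. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and does
not demonstrate.

## Problem setting and data model

The input is what a pose estimator produces from a side-view recording of a
seated eater: per frame, eight upper-body joints (nose, neck, both
shoulder/elbow/wrist chains) and four mouth landmarks (corners A/C, upper- and
lower-lip middles B/D), each an `(x, y, confidence)` triple in pixel
coordinates (default 720x576 at 25 fps). Real pose output is degraded by
missing detections, low-confidence points and single-frame glitches; all three
are modelled explicitly.

Two annotation sources share one event vocabulary: `meal_start`, `meal_stop`,
`spoonful` (food leaves the plate), `food_addition`, and `bite`. Manual logs
contain all five; the detector emits bites only. Meal duration is therefore
anchored differently by source — first spoonful to last bite for manual logs,
first to last detected bite for detected logs — and the difference is kept
explicit rather than hidden.

## Preprocessing

1. **Cleaning.** A detection is discarded when its confidence is below
   `confidence_floor` (default 0.1) or when it jumps more than
   `jump_fraction` (default 0.15) of the frame diagonal in one frame *and*
   returns next frame (a one-frame spike; sustained moves are kept, so fast
   genuine gestures survive). Every missing value is then filled with the
   previous frame's value, with leading gaps back-filled. The operation is
   idempotent; a point never detected at all raises an error naming it.
2. **Smoothing.** Each coordinate trajectory is replaced by a cubic smoothing
   spline. The penalty is selected per trajectory by cross-validation: for
   trajectories over 600 frames, candidate penalties on a 13-point log grid
   (1e-6..1e6) are fitted to every `stride`-th sample and scored on the
   skipped samples, the winner rescaled by the stride and refitted on the
   full trajectory; shorter trajectories use generalized cross-validation
   directly. `spline_smoothing=0` degenerates to an interpolating spline
   (identity at the frames).
3. **Side selection.** The eater is filmed from one side, so only one mouth
   corner is reliably visible; the corner (A=left, C=right) with the higher
   mean detection confidence is used, ties going left.
4. **Features.** Body stream (44 per frame): the 8 joints in neck-origin
   coordinates plus all 28 pairwise inter-joint distances. Mouth stream
   (9 per frame): B, D and the selected corner in nose-origin coordinates
   plus their 3 pairwise distances. Re-origining makes both streams exactly
   translation invariant; features stay in pixels (no scale normalization —
   apparent size carries information at a fixed camera distance), with an
   optional per-meal z-scoring switch, off by default. The paired-distance
   reading of "coordinates and the distances between them" is the superset
   interpretation; the exact vector layouts are fixed in
   `BODY_FEATURE_NAMES` / `MOUTH_FEATURE_NAMES`.

## The two-stream classifier

The detector answers: does this 2-second window contain a bite? Each stream
(body, mouth) passes through two convolutional blocks — two same-padded
temporal convolutions (ReLU) then max pooling — followed by an LSTM stack
whose final hidden state summarizes the window; the two summaries are
concatenated, fused by a dense layer, and mapped to a single bite logit.
The network, including backpropagation and Adam, is implemented directly in
NumPy; gradient correctness is verified against numerical differencing in
the test suite, and training is bit-reproducible given the seed.

Defaults (all in `ModelConfig`): conv blocks (32, k3) and (64, k3), pool 2,
LSTM 64 -> 32, fusion 32, dropout 0.1, Adam at 1e-3, batch 64, 15 epochs.
These widths train in a couple of minutes on one CPU core; the block
structure, not the widths, is what the architecture fixes. Inputs are
standardized per feature with training-set statistics stored in the model
(pixel-scale inputs otherwise stall optimization). Class weighting
multiplies positive-clip losses by the observed non-bite/bite ratio.

**Training clips**: one positive window centred on each annotated bite;
negatives tiled every `negative_stride_s` (default 2 s) over regions whose
centre is at least one window length from every bite — at realistic bite
densities this yields roughly 2-2.5 non-bite clips per bite clip, the
imbalance the class weighting mirrors. The corpus is split 90/10 stratified
by label, the 10% held out for clip-level evaluation.

**Inference**: the window slides over the whole meal with a step of one
frame; each window's probability is assigned to its centre frame (symmetric
evidence), edge frames replicate the nearest computed value. Batched
evaluation equals the naive per-window loop to float precision.

## From probability signal to bite events

1. Median-filter the signal (`median_window_s` = 0.52 s, i.e. 13 frames at
   25 fps, forced odd). The filter replicates edge values rather than
   zero-padding, which keeps the whole step equivariant under positive
   affine maps of the signal.
2. Threshold at `mean + k*SD` of the filtered signal (k = 1). This adapts
   per meal and needs no calibration data, but it presumes bites are
   sparse: the signal must spend most of the meal near baseline. It also
   implies a flat signal yields no detections (nothing strictly exceeds its
   own mean).
3. Local maxima strictly above the threshold. Median filtering flattens
   peaks into short plateaus, so a maximum is a maximal run of equal values
   strictly above both neighbours, anchored at the run's middle frame (the
   apex of a symmetric bump); runs touching the signal boundary don't count.
4. Prune maxima closer than `min_separation_s` (default 1.0 s) greedily,
   keeping the higher value (ties to the earlier). Detected bites are the
   survivors' frame times.

## Meal analytics

Per meal: duration (minutes), total bites, bite counts per tenth of the meal
(half-open segments, the last closed so counts always sum to the total), and
an ordinary least-squares quadratic `y = y0 + a*x + b*x**2` over segment
index `x = 1..10`. The segment *index* (not the midpoint fraction) is the
regressor; any affine re-parameterisation changes the coefficients, so the
convention is fixed. The fit is exact (RSS 0) on noiseless quadratic input.
Meals with higher bite rates at both ends show up as `a < 0, b > 0` with the
minimum in the middle segments.

Agreement statistics: Cohen's kappa, recall, specificity and *two* F1
variants on clip labels — `f1_bite`, the standard precision/recall harmonic
mean on the bite class, and `f1_rs`, the recall/specificity harmonic mean.
Both are computed and labelled because the two are easily conflated when
only a single "F1" is quoted; `f1_bite` is the headline number here.
Event-level agreement uses maximum one-to-one matching of detected to
reference bites within ±1 s (a two-pointer scan on sorted times, which is
optimal on a line and is verified against exhaustive assignment in tests).
Per-meal measures are compared by Pearson correlation with qualitative bands
at R² ≥ 0.50 / 0.75 / 0.90.

## The synthetic generator

No keypoint recordings of real meals ship with the package, so the generator
produces the study conditions every stage is tested under:

* **Bite times** follow a quadratic per-segment rate profile: for each tenth
  of the meal a Poisson count with the profile's mean, placed uniformly in
  the segment; a 1.5 s refractory gap is enforced by re-drawing the later
  bite of an offending pair within its own segment (re-drawing positions
  rather than rejecting whole placements keeps the counts exactly Poisson).
  The default profile (6.909, -0.7409, 0.0683) integrates to ~54.6 bites —
  a typical observed meal — and its U-shape (frequent bites at meal start
  and end) is the pattern the analytics stage must recover.
* **Kinematics**: each bite is a plate-to-mouth-and-back reach of the
  dominant wrist with cubic ease-in/ease-out, peaking exactly at the
  (frame-aligned) bite time, with the mouth aperture (B-D distance) opening
  in phase; the elbow follows at reduced amplitude; a slow rigid whole-body
  sway is added (rigid, so features are unaffected — it exercises the
  smoothing stage without touching the ground truth).
* **Degradations**: Gaussian jitter (default 1.5 px), per-point dropout
  (0.02), one-frame uniform-position spikes (0.005), and a low-confidence
  rendering of the mouth corner facing away from the camera (so side
  selection has a ground truth).

What the generator does **not** model: chewing and drinking gestures,
utensil-specific trajectories, posture changes, occlusions lasting many
frames, food-addition kinematics, multi-person scenes, or correlated
pose-estimator failures. Passing the synthetic benchmark therefore shows the
pipeline machinery is correct and self-consistent — that a detector trained
on annotated keypoint meals recovers events, counts, durations and rate
curves faithfully when the gesture structure is present — not that the
shipped defaults would reach the same numbers on arbitrary real video.

## Benchmark conditions

The end-to-end benchmark simulates 20 meals of 240 s. Bite density is what
the mean-plus-SD threshold implicitly assumes, so the rate profile is scaled
with duration (half-length meals get half the counts), holding density at
the ~55-bites-per-8-minutes level of real meals; 240 s keeps a full
single-core run (simulation, preprocessing, training, stride-1 inference
over ~120k windows) in the minutes range. Held-out clip kappa, event-level
F1 (±1 s) and per-meal bite-count/duration correlations are reported;
`scripts/acceptance.py` recomputes all of them from scratch.

## Known limitations

* The classifier is trained per corpus; no pretrained weights ship.
* The detector emits bites only; spoonfuls and food additions remain
  manual-annotation events, which is why detected meal duration is anchored
  at first-to-last bite.
* The mean+SD threshold degrades when bites are so dense that the signal's
  baseline fraction shrinks (very short, very fast meals), or for meals with
  long bite-free tails that deflate the mean.
* Matching tolerance (±1 s), separation (1 s) and the threshold multiplier
  (k=1) are exposed in config; the defaults suit 25 fps recordings of
  utensil meals.
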