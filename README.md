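# bitekit

Automatic bite detection and meal-microstructure analysis from pose
keypoints of videotaped meals.

## What problem this solves

Objective eating-behaviour research scores meal videos by hand: a trained
annotator logs every bite (the moment food enters the mouth), spoonful and
food addition, and meal duration and total bites are derived from that log.
Manual annotation is slow — typically longer than the meals themselves — and
limits study size. `bitekit` replaces the bite-annotation step: given
per-frame 2-D skeletal and mouth keypoints of the eater (as produced by a
pose estimator from a side-view recording), it emits a timestamped bite log
and the behavioural measures built on it, plus the agreement statistics
needed to validate the automatic log against a manual one.

It is aimed at researchers in ingestive behaviour, obesity and
eating-disorder research who already work with recorded laboratory meals.

## Method in brief

* **Features.** Eight upper-body joints re-origined at the neck plus all
  pairwise inter-joint distances (44 values/frame), and three mouth points
  (upper lip B, lower lip D, visible corner A or C) re-origined at the nose
  plus their distances (9 values/frame). Streams are cleaned (confidence
  floor, one-frame spike removal, previous-frame fill) and smoothed by
  cross-validated cubic splines.
* **Classifier.** A two-stream network over 2-s windows: per stream, two
  convolutional blocks (two temporal convolutions + max pooling) feed an
  LSTM stack whose final state summarizes the window; the body and mouth
  summaries are concatenated and fused by a dense layer into one bite
  probability. Implemented in NumPy (training included, deterministic by
  seed).
* **Event extraction.** Sliding the window at a 1-frame step gives a
  per-frame probability signal; it is median-filtered, thresholded at its
  mean + 1 SD, and local maxima closer than 1 s are pruned keeping the
  higher — the survivors are the detected bites.
* **Analytics.** Meal duration, total bites, bite counts per 10% meal
  segment, and an OLS quadratic `y = y0 + a·x + b·x²` (x = segment 1..10)
  describing how the bite rate changes as the meal progresses.
* **Agreement.** Cohen's κ / recall / specificity / F1 variants on clip
  labels, ±1 s event matching, and Pearson correlations of per-meal
  measures.

Since no keypoint recordings ship with the package, a synthetic generator
(`bitekit.synth`) renders meals with the full structure the detector relies
on — quadratic bite-rate profiles, plate-to-mouth wrist reaches with mouth
aperture opening, pose-estimator-style noise — so the entire pipeline is
testable end to end. See `docs/methods.md` for the details and the
generator's limits.

## Worked example

```python
import numpy as np
from bitekit import (
    SimConfig, simulate_meal, clean_sequence, smooth_sequence,
    select_mouth_side, assemble_features, extract_labeled_clips,
    split_clips, train_model, probability_signal, extract_bites,
    meal_summary, match_events, ModelConfig,
)

# one simulated 4-minute meal at realistic bite density
profile = tuple(c * 0.5 for c in (6.909, -0.7409, 0.0683))
seq, truth = simulate_meal(SimConfig(duration_s=240.0, rate_profile=profile, seed=5))

seq = smooth_sequence(clean_sequence(seq))
feats = assemble_features(seq, select_mouth_side(seq))

clips = extract_labeled_clips(feats, truth)
train, heldout = split_clips(clips, seed=0)
model = train_model(train, ModelConfig(epochs=10, seed=0))

detected = extract_bites(probability_signal(model, feats))
s = meal_summary(detected)
m = match_events(detected.bite_times(), truth.bite_times(), tolerance_s=1.0)
print(f"true bites: {len(truth.bite_times())}  detected: {s.total_bites}")
print(f"duration: {s.duration_min:.2f} min  event F1: {m.f1:.3f}")
```

Output:

```
true bites: 25  detected: 24
duration: 3.89 min  event F1: 0.980
```

24 of the 25 simulated bites are recovered within ±1 s — the missed one sits
too close to the meal boundary for a full 2-s window (training and evaluating
on the same meal, as a smoke example; the benchmark below holds out data
properly). The detected duration spans first to last detected bite, slightly
shorter than the annotated meal, which starts at the first spoonful.

The same flow is available from the shell:

```bash
bitekit run-all --config config.yaml --seed 1 --out-dir out/
```

with stages `simulate | preprocess | make-clips | train | detect | analyze |
evaluate` also runnable individually; every stage writes a manifest (config
hash, seed, version) so reruns are reproducible.

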