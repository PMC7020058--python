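"""End-to-end synthetic benchmark: simulate, train, detect, evaluate.

Runs the full pipeline in memory on a corpus of simulated meals and
reports the agreement statistics a validation study would: held-out
clip-level confusion metrics (Cohen's kappa, recall, specificity, both F1
variants), event-level precision/recall/F1 of detected vs true bite
timestamps, per-meal total-bite and duration correlations, mean meal
measures and the quadratic bite-rate fits of both annotation sources.

Default corpus: 20 meals of 240 s at 25 fps.  The per-segment rate profile
is scaled with the meal duration (half-length meals get half the counts),
so the per-second bite density — which the mean-plus-SD detection
threshold implicitly assumes — stays at the level of real ~8-minute meals
with ~55 bites, while a single-CPU run stays in the minutes range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analytics import average_segment_profile, fit_quadratic, meal_summary
from .detector import (
    ClipSet,
    ModelConfig,
    PostprocessConfig,
    extract_bites,
    extract_labeled_clips,
    probability_signal,
    split_clips,
    train_model,
)
from .evaluation import ConfusionMatrix, confusion_metrics, correlate_measures, match_events
from .preprocess import CleaningConfig, assemble_features, clean_sequence, select_mouth_side, smooth_sequence
from .synth import DEFAULT_RATE_PROFILE, SimConfig, simulate_meal

#: Meal length whose per-second bite density the default rate profile encodes.
REFERENCE_DURATION_S = 480.0

__all__ = ["BenchmarkResult", "run_benchmark"]


@dataclass
class BenchmarkResult:
    clip_metrics: dict
    n_eval_clips: int
    n_train_clips: int
    event: dict
    bite_count_r: float
    duration_r: float
    n_meals: int
    mean_duration_min_true: float
    mean_duration_min_detected: float
    mean_bites_true: float
    mean_bites_detected: float
    fit_true: tuple[float, float, float]
    fit_detected: tuple[float, float, float]
    per_meal: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "clip_metrics": self.clip_metrics,
            "n_eval_clips": self.n_eval_clips,
            "n_train_clips": self.n_train_clips,
            "event": self.event,
            "bite_count_r": self.bite_count_r,
            "duration_r": self.duration_r,
            "n_meals": self.n_meals,
            "mean_duration_min_true": self.mean_duration_min_true,
            "mean_duration_min_detected": self.mean_duration_min_detected,
            "mean_bites_true": self.mean_bites_true,
            "mean_bites_detected": self.mean_bites_detected,
            "fit_true": list(self.fit_true),
            "fit_detected": list(self.fit_detected),
        }


def run_benchmark(
    n_meals: int = 20,
    duration_s: float = 240.0,
    seed: int = 1,
    model_cfg: ModelConfig | None = None,
    post_cfg: PostprocessConfig | None = None,
    cleaning_cfg: CleaningConfig | None = None,
    train_fraction: float = 0.9,
    match_tolerance_s: float = 1.0,
    verbose: bool = False,
) -> BenchmarkResult:
    """Simulate a meal corpus, train the detector and measure agreement.

    All randomness (per-meal simulation seeds, the train/eval split and
    network initialization/shuffling) derives from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    meal_seeds, split_seed, model_seed = ss.spawn(3)
    meal_seed_vals = meal_seeds.generate_state(n_meals) % (2**31)

    cleaning_cfg = cleaning_cfg or CleaningConfig()
    post_cfg = post_cfg or PostprocessConfig()
    if model_cfg is None:
        model_cfg = ModelConfig(seed=int(model_seed.generate_state(1)[0] % (2**31)))

    # hold per-second bite density at the reference level for any duration
    scale = duration_s / REFERENCE_DURATION_S
    profile = tuple(c * scale for c in DEFAULT_RATE_PROFILE)

    feats = []
    truth_logs = []
    clip_sets = []
    for i in range(n_meals):
        cfg = SimConfig(duration_s=duration_s, rate_profile=profile,
                        seed=int(meal_seed_vals[i]))
        seq, truth = simulate_meal(cfg)
        seq = clean_sequence(seq, cleaning_cfg)
        seq = smooth_sequence(seq, cleaning_cfg)
        side = select_mouth_side(seq)
        f = assemble_features(seq, side, meal_id=f"meal{i:02d}")
        feats.append(f)
        truth_logs.append(truth)
        clip_sets.append(extract_labeled_clips(f, truth, meal_id=f"meal{i:02d}"))
        if verbose:
            print(f"simulated meal {i + 1}/{n_meals}: {len(truth.bite_times())} bites")

    clips = ClipSet.concatenate(clip_sets)
    train_set, eval_set = split_clips(
        clips, train_fraction=train_fraction,
        seed=int(split_seed.generate_state(1)[0] % (2**31)),
    )
    model = train_model(train_set, model_cfg)
    if verbose:
        print(f"trained on {len(train_set)} clips; history={model.history['accuracy'][-3:]}")

    # clip-level agreement on the held-out split
    probs = model.predict_proba(eval_set.body, eval_set.mouth)
    pred = probs >= 0.5
    truth_lab = eval_set.labels == 1
    cm = ConfusionMatrix(
        tp=int(np.sum(pred & truth_lab)),
        fn=int(np.sum(~pred & truth_lab)),
        fp=int(np.sum(pred & ~truth_lab)),
        tn=int(np.sum(~pred & ~truth_lab)),
    )
    clip_metrics = confusion_metrics(cm)

    # whole-meal inference and event-level agreement
    tp = fp = fn = 0
    bite_pairs = []
    duration_pairs = []
    true_profiles = []
    det_profiles = []
    per_meal = []
    for f, truth in zip(feats, truth_logs):
        sig = probability_signal(model, f)
        detected = extract_bites(sig, post_cfg)
        m = match_events(detected.bite_times(), truth.bite_times(),
                         tolerance_s=match_tolerance_s)
        tp += m.tp
        fp += m.fp
        fn += m.fn
        s_true = meal_summary(truth)
        true_profiles.append(s_true.segment_counts)
        bite_true = s_true.total_bites
        if len(detected.bite_times()):
            s_det = meal_summary(detected)
            det_profiles.append(s_det.segment_counts)
            bite_det = s_det.total_bites
            dur_det = s_det.duration_min
        else:
            bite_det, dur_det = 0, 0.0
        bite_pairs.append((bite_true, bite_det))
        duration_pairs.append((s_true.duration_min, dur_det))
        per_meal.append({"true_bites": bite_true, "detected_bites": bite_det,
                         "match": m.to_dict()})
        if verbose:
            print(f"{f.meal_id}: true={bite_true} det={bite_det} f1={m.f1:.3f}")

    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    bite_r = correlate_measures(bite_pairs).r
    duration_r = correlate_measures(duration_pairs).r
    fit_true = fit_quadratic(average_segment_profile(true_profiles))
    fit_det = fit_quadratic(average_segment_profile(det_profiles))

    return BenchmarkResult(
        clip_metrics=clip_metrics.to_dict(),
        n_eval_clips=len(eval_set),
        n_train_clips=len(train_set),
        event={"precision": precision, "recall": recall, "f1": f1,
               "tp": tp, "fp": fp, "fn": fn},
        bite_count_r=bite_r,
        duration_r=duration_r,
        n_meals=n_meals,
        mean_duration_min_true=float(np.mean([p[0] for p in duration_pairs])),
        mean_duration_min_detected=float(np.mean([p[1] for p in duration_pairs])),
        mean_bites_true=float(np.mean([p[0] for p in bite_pairs])),
        mean_bites_detected=float(np.mean([p[1] for p in bite_pairs])),
        fit_true=fit_true.coefficients(),
        fit_detected=fit_det.coefficients(),
        per_meal=per_meal,
    )
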