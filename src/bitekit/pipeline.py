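"""Configuration and the staged pipeline tying the modules together.

One YAML config drives everything.  Blocks (all optional, defaults apply):

.. code-block:: yaml

    seed: 1
    n_meals: 5
    simulate:      { duration_s: 240.0, fps: 25.0, jitter_px: 1.5, ... }
    cleaning:      { confidence_floor: 0.1, jump_fraction: 0.15, ... }
    model:         { epochs: 15, lstm_units: [64, 32], ... }
    postprocess:   { median_window_s: 0.52, threshold_k: 1.0, ... }
    clips:         { window_s: 2.0, negative_stride_s: 0.5 }
    evaluation:    { tolerance_s: 1.0 }

Stages write their artifacts under the output directory and record a
manifest (config hash, seed, package version, inputs) next to each, so a
rerun with the same config and seed reproduces identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .analytics import meal_summary
from .detector import (
    ClipSet,
    ModelConfig,
    PostprocessConfig,
    TrainedModel,
    extract_bites,
    extract_labeled_clips,
    probability_signal,
    split_clips,
    train_model,
)
from .evaluation import ConfusionMatrix, confusion_metrics, correlate_measures, match_events
from .keypoint_io import (
    read_annotations,
    read_keypoints,
    write_annotations,
    write_behavior_log,
    write_keypoints,
)
from .preprocess import (
    CleaningConfig,
    TwoStreamFeatures,
    assemble_features,
    clean_sequence,
    select_mouth_side,
    smooth_sequence,
)
from .synth import SimConfig, simulate_meal

log = logging.getLogger("bitekit")

STAGES = ("simulate", "preprocess", "make-clips", "train", "detect", "analyze", "evaluate")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    """A stage cannot run; the message names what to run first."""


def _build(cls, block: dict, **extra):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(block) - known
    if bad:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(bad)}")
    merged = {**block, **extra}
    for key, val in merged.items():
        if isinstance(val, list):
            merged[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
    return cls(**merged)


@dataclasses.dataclass
class PipelineConfig:
    """Validated per-stage configuration blocks plus global settings."""

    seed: int = 1
    n_meals: int = 5
    simulate: dict = dataclasses.field(default_factory=dict)
    cleaning: dict = dataclasses.field(default_factory=dict)
    model: dict = dataclasses.field(default_factory=dict)
    postprocess: dict = dataclasses.field(default_factory=dict)
    clips: dict = dataclasses.field(default_factory=dict)
    evaluation: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        # every block must validate before any stage runs
        self.sim_config(0)
        self.cleaning_config()
        self.model_config()
        self.postprocess_config()
        self.clip_options()
        self.evaluation_options()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config block(s): {sorted(bad)}")
        return cls(**doc)

    def sim_config(self, meal_index: int) -> SimConfig:
        seed = int(np.random.SeedSequence([self.seed, meal_index]).generate_state(1)[0] % (2**31))
        return _build(SimConfig, self.simulate, seed=seed)

    def cleaning_config(self) -> CleaningConfig:
        return _build(CleaningConfig, self.cleaning)

    def model_config(self) -> ModelConfig:
        return _build(ModelConfig, self.model, seed=self.model.get("seed", self.seed))

    def postprocess_config(self) -> PostprocessConfig:
        return _build(PostprocessConfig, self.postprocess)

    def clip_options(self) -> dict:
        opts = {"window_s": 2.0, "negative_stride_s": 2.0, "train_fraction": 0.9}
        bad = set(self.clips) - set(opts)
        if bad:
            raise ValueError(f"unknown clips option(s): {sorted(bad)}")
        opts.update(self.clips)
        return opts

    def evaluation_options(self) -> dict:
        opts = {"tolerance_s": 1.0}
        bad = set(self.evaluation) - set(opts)
        if bad:
            raise ValueError(f"unknown evaluation option(s): {sorted(bad)}")
        opts.update(self.evaluation)
        return opts

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _manifest(out_dir: Path, stage: str, cfg: PipelineConfig, inputs: Sequence[str]) -> None:
    doc = {
        "stage": stage,
        "config_sha256_16": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
        "inputs": sorted(str(i) for i in inputs),
    }
    (out_dir / f"manifest_{stage.replace('-', '_')}.json").write_text(
        json.dumps(doc, indent=2, sort_keys=True) + "\n"
    )


def _meal_ids(cfg: PipelineConfig) -> list[str]:
    return [f"meal{i:02d}" for i in range(cfg.n_meals)]


def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{stage}' needs {path.name}; run the '{producer}' stage first"
        )
    return path


def _load_features(path: Path) -> TwoStreamFeatures:
    with np.load(path) as data:
        return TwoStreamFeatures(
            body_stream=data["body"],
            mouth_stream=data["mouth"],
            fps=float(data["fps"]),
            side=str(data["side"]),
            meal_id=str(data["meal_id"]),
        )


def run_pipeline(
    cfg: PipelineConfig, stages: Sequence[str], out_dir
) -> dict:
    """Run the requested stages in dependency order; returns a result dict.

    Artifacts land under ``out_dir``: keypoints and true annotations from
    ``simulate``, feature matrices from ``preprocess``, the clip store from
    ``make-clips``, the model from ``train``, detected-bite logs from
    ``detect``, per-meal summaries from ``analyze`` and agreement metrics
    from ``evaluate``.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    ids = _meal_ids(cfg)

    if "simulate" in stages:
        log.info("simulate: %d meals", cfg.n_meals)
        for i, mid in enumerate(ids):
            seq, truth = simulate_meal(cfg.sim_config(i))
            write_keypoints(seq, out_dir / f"{mid}.keypoints.json", "json_frames")
            write_annotations(truth, out_dir / f"{mid}.truth.csv")
        _manifest(out_dir, "simulate", cfg, [])

    if "preprocess" in stages:
        ccfg = cfg.cleaning_config()
        for mid in ids:
            path = _require(out_dir / f"{mid}.keypoints.json", "preprocess", "simulate")
            seq = read_keypoints(path, "json_frames")
            seq = smooth_sequence(clean_sequence(seq, ccfg), ccfg)
            side = select_mouth_side(seq)
            feats = assemble_features(seq, side, zscore=ccfg.zscore, meal_id=mid)
            np.savez(
                out_dir / f"{mid}.features.npz",
                body=feats.body_stream,
                mouth=feats.mouth_stream,
                fps=feats.fps,
                side=feats.side,
                meal_id=mid,
            )
            log.info("preprocess: %s (side=%s)", mid, side)
        _manifest(out_dir, "preprocess", cfg, [f"{m}.keypoints.json" for m in ids])

    if "make-clips" in stages:
        opts = cfg.clip_options()
        sets = []
        for mid in ids:
            fpath = _require(out_dir / f"{mid}.features.npz", "make-clips", "preprocess")
            tpath = _require(out_dir / f"{mid}.truth.csv", "make-clips", "simulate")
            feats = _load_features(fpath)
            truth = read_annotations(tpath)
            sets.append(
                extract_labeled_clips(
                    feats, truth, window_s=opts["window_s"],
                    negative_stride_s=opts["negative_stride_s"], meal_id=mid,
                )
            )
        clips = ClipSet.concatenate(sets)
        np.savez(
            out_dir / "clips.npz",
            body=clips.body,
            mouth=clips.mouth,
            labels=clips.labels,
            meal=[p[0] for p in clips.provenance],
            start=[p[1] for p in clips.provenance],
            fps=clips.fps,
        )
        log.info("make-clips: %d clips (%d positive)", len(clips), int(clips.labels.sum()))
        _manifest(out_dir, "make-clips", cfg, [f"{m}.features.npz" for m in ids])

    if "train" in stages:
        cpath = _require(out_dir / "clips.npz", "train", "make-clips")
        with np.load(cpath) as data:
            clips = ClipSet(
                body=data["body"],
                mouth=data["mouth"],
                labels=data["labels"],
                provenance=tuple(zip(data["meal"].tolist(), data["start"].tolist())),
                fps=float(data["fps"]),
            )
        train_set, eval_set = split_clips(
            clips, train_fraction=cfg.clip_options()["train_fraction"], seed=cfg.seed
        )
        model = train_model(train_set, cfg.model_config())
        model.save(out_dir / "model.npz")
        probs = model.predict_proba(eval_set.body, eval_set.mouth)
        pred, truth_lab = probs >= 0.5, eval_set.labels == 1
        cm = ConfusionMatrix(
            tp=int(np.sum(pred & truth_lab)),
            fn=int(np.sum(~pred & truth_lab)),
            fp=int(np.sum(pred & ~truth_lab)),
            tn=int(np.sum(~pred & ~truth_lab)),
        )
        clip_eval = {
            "n_train": len(train_set),
            "n_eval": len(eval_set),
            "matrix": dataclasses.asdict(cm),
            "metrics": confusion_metrics(cm).to_dict(),
            "final_train_accuracy": model.history["accuracy"][-1],
        }
        (out_dir / "clip_eval.json").write_text(json.dumps(clip_eval, indent=2) + "\n")
        results["clip_eval"] = clip_eval
        log.info("train: held-out clip kappa %.3f", clip_eval["metrics"]["kappa"])
        _manifest(out_dir, "train", cfg, ["clips.npz"])

    if "detect" in stages:
        mpath = _require(out_dir / "model.npz", "detect", "train")
        model = TrainedModel.load(mpath)
        pcfg = cfg.postprocess_config()
        for mid in ids:
            fpath = _require(out_dir / f"{mid}.features.npz", "detect", "preprocess")
            feats = _load_features(fpath)
            if feats.fps != model.fps:
                raise PipelineError(
                    f"fps mismatch: model trained at {model.fps}, {mid} is {feats.fps}"
                )
            sig = probability_signal(model, feats)
            detected = extract_bites(sig, pcfg)
            write_annotations(detected, out_dir / f"{mid}.detected.csv")
            log.info("detect: %s -> %d bites", mid, len(detected.bite_times()))
        _manifest(out_dir, "detect", cfg, ["model.npz"] + [f"{m}.features.npz" for m in ids])

    if "analyze" in stages:
        for mid in ids:
            for kind, source in (("truth", "manual"), ("detected", "detected")):
                path = out_dir / f"{mid}.{kind}.csv"
                if kind == "truth":
                    _require(path, "analyze", "simulate")
                elif not path.exists():
                    continue
                events = read_annotations(path, source=source)
                if len(events.bite_times()) == 0:
                    continue
                summary = meal_summary(events)
                write_behavior_log(summary, events, out_dir / f"{mid}.{kind}.log.csv")
        _manifest(out_dir, "analyze", cfg, [f"{m}.truth.csv" for m in ids])

    if "evaluate" in stages:
        tol = cfg.evaluation_options()["tolerance_s"]
        tp = fp = fn = 0
        bite_pairs = []
        duration_pairs = []
        for mid in ids:
            tpath = _require(out_dir / f"{mid}.truth.csv", "evaluate", "simulate")
            dpath = _require(out_dir / f"{mid}.detected.csv", "evaluate", "detect")
            truth = read_annotations(tpath, source="manual")
            detected = read_annotations(dpath, source="detected")
            m = match_events(detected.bite_times(), truth.bite_times(), tolerance_s=tol)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
            s_true = meal_summary(truth)
            n_det = len(detected.bite_times())
            s_det = meal_summary(detected) if n_det else None
            bite_pairs.append((s_true.total_bites, n_det))
            duration_pairs.append(
                (s_true.duration_min, s_det.duration_min if s_det else 0.0)
            )
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        def _safe_r(pairs):
            arr = np.asarray(pairs, dtype=float)
            if len(arr) < 3 or np.isclose(arr[:, 0].std(), 0) or np.isclose(arr[:, 1].std(), 0):
                return None
            return correlate_measures(pairs).r

        metrics = {
            "event": {"precision": precision, "recall": recall, "f1": f1,
                      "tp": tp, "fp": fp, "fn": fn, "tolerance_s": tol},
            "bite_count_r": _safe_r(bite_pairs),
            "duration_r": _safe_r(duration_pairs),
        }
        (out_dir / "evaluation.json").write_text(json.dumps(metrics, indent=2) + "\n")
        results["evaluation"] = metrics
        log.info("evaluate: event F1 %.3f", f1)
        _manifest(out_dir, "evaluate", cfg, [f"{m}.detected.csv" for m in ids])

    return results
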