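"""Clip construction, classifier training, sliding-window inference and
probability-signal post-processing.

The detector answers one question — "does this 2-second window of body and
mouth features contain a bite?" — and everything else is built around it:

* Training clips are cut from annotated meals: one positive window centred
  on every annotated bite, negative windows tiled over stretches of the
  meal whose centre is at least a window length away from every bite.
* A two-stream conv+LSTM network (see :mod:`bitekit.nn`) is trained on a
  stratified 90/10 split with class weighting against the bite/non-bite
  imbalance.
* Whole-meal inference slides the window with a step of one frame, giving
  a per-frame bite-probability signal anchored at the window centre.
* The signal is median-filtered; the threshold is the signal's mean plus
  ``k`` standard deviations; local maxima above the threshold that are too
  close together are pruned keeping the higher one.  Surviving maxima are
  the detected bites.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.special import expit as sigmoid

from .keypoint_io import AnnotationLog
from .nn import Adam, TwoStreamNet, weighted_bce_with_logits
from .preprocess import TwoStreamFeatures

__all__ = [
    "ClipSet",
    "ModelConfig",
    "PostprocessConfig",
    "ProbabilitySignal",
    "TrainedModel",
    "extract_labeled_clips",
    "split_clips",
    "train_model",
    "probability_signal",
    "extract_bites",
    "local_maxima",
]


@dataclass
class ClipSet:
    """Fixed-length labelled training windows for both streams.

    ``body``/``mouth`` have shape (n_clips, window_frames, n_features);
    ``labels`` is 1 for bite, 0 for non-bite; ``provenance`` records
    (meal_id, start_frame) per clip.
    """

    body: np.ndarray
    mouth: np.ndarray
    labels: np.ndarray
    provenance: tuple[tuple[str, int], ...]
    fps: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")
        n = self.labels.shape[0]
        if self.body.shape[0] != n or self.mouth.shape[0] != n or len(self.provenance) != n:
            raise ValueError("clip arrays and provenance lengths differ")
        if self.body.shape[1] != self.mouth.shape[1]:
            raise ValueError("body and mouth windows differ in length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def window_frames(self) -> int:
        return self.body.shape[1]

    def subset(self, idx: np.ndarray) -> "ClipSet":
        return ClipSet(
            body=self.body[idx],
            mouth=self.mouth[idx],
            labels=self.labels[idx],
            provenance=tuple(self.provenance[i] for i in np.atleast_1d(idx)),
            fps=self.fps,
        )

    @staticmethod
    def concatenate(sets: Sequence["ClipSet"]) -> "ClipSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        fps = sets[0].fps
        if any(s.fps != fps for s in sets):
            raise ValueError("clip sets disagree on fps")
        return ClipSet(
            body=np.concatenate([s.body for s in sets]),
            mouth=np.concatenate([s.mouth for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            provenance=tuple(p for s in sets for p in s.provenance),
            fps=fps,
        )


@dataclass
class ModelConfig:
    """Architecture and optimization settings of the bite classifier.

    The shape is fixed — two convolutional blocks per stream (each two
    same-padded temporal convolutions plus max pooling), an LSTM stack
    whose final state summarizes the window, and a dense fusion of the two
    streams — while widths, learning rate and schedule are tunable.  The
    defaults train in minutes on a single CPU core.
    """

    conv_blocks: tuple[tuple[int, int], ...] = ((32, 3), (64, 3))
    pool_size: int = 2
    lstm_units: tuple[int, ...] = (64, 32)
    fusion_units: int = 32
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 15
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != 2:
            raise ValueError("exactly two conv blocks per stream")
        if len(self.lstm_units) < 1:
            raise ValueError("at least one LSTM layer required")
        if any(v <= 0 for v in (self.pool_size, self.fusion_units, self.batch_size,
                                self.epochs, self.learning_rate)):
            raise ValueError("sizes, epochs and learning rate must be positive")


@dataclass
class ProbabilitySignal:
    """Per-frame bite probability for one meal."""

    values: np.ndarray
    fps: float
    meal_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if len(self.values) and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PostprocessConfig:
    """Signal-to-events settings.

    median_window_s : median filter span (rounded to an odd frame count;
        0.52 s is 13 frames at 25 fps).
    threshold_k : the detection threshold is mean + k*SD of the filtered
        signal (k = 1 reproduces the mean-plus-standard-deviation rule).
    min_separation_s : maxima closer than this keep only the higher one.
    """

    median_window_s: float = 0.52
    threshold_k: float = 1.0
    min_separation_s: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_k < 0:
            raise ValueError("threshold_k must be non-negative")
        if not self.min_separation_s > 0:
            raise ValueError("min_separation_s must be positive")

    def median_frames(self, fps: float) -> int:
        k = max(1, int(round(self.median_window_s * fps)))
        return k if k % 2 == 1 else k + 1


class _Scaler:
    """Per-feature standardization fitted on training clips."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = mean
        std = std.copy()
        std[std == 0] = 1.0
        self.std = std

    @classmethod
    def fit(cls, clips: np.ndarray) -> "_Scaler":
        flat = clips.reshape(-1, clips.shape[-1])
        return cls(flat.mean(axis=0), flat.std(axis=0))

    def __call__(self, clips: np.ndarray) -> np.ndarray:
        return (clips - self.mean) / self.std


@dataclass
class TrainedModel:
    """A trained two-stream classifier plus its input scalers and history."""

    net: TwoStreamNet
    config: ModelConfig
    body_scaler: _Scaler
    mouth_scaler: _Scaler
    window_frames: int
    fps: float
    history: dict = field(default_factory=dict)

    def predict_proba(self, body: np.ndarray, mouth: np.ndarray) -> np.ndarray:
        """Bite probability for a batch of (n, window, features) windows."""
        return self.net.predict_proba(self.body_scaler(body), self.mouth_scaler(mouth))

    def save(self, path) -> None:
        """Write weights (npz) plus a JSON sidecar with the configuration."""
        path = Path(path)
        if path.suffix != ".npz":
            path = Path(str(path) + ".npz")
        state = self.net.state_dict()
        np.savez(
            path,
            **state,
            __body_mean=self.body_scaler.mean,
            __body_std=self.body_scaler.std,
            __mouth_mean=self.mouth_scaler.mean,
            __mouth_std=self.mouth_scaler.std,
        )
        sidecar = {
            "config": asdict(self.config),
            "window_frames": self.window_frames,
            "fps": self.fps,
            "history": self.history,
            "body_dim": int(self.body_scaler.mean.shape[0]),
            "mouth_dim": int(self.mouth_scaler.mean.shape[0]),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        meta = json.loads(Path(str(npz_path) + ".json").read_text())
        cfg_doc = meta["config"]
        cfg = ModelConfig(
            conv_blocks=tuple(tuple(b) for b in cfg_doc["conv_blocks"]),
            pool_size=cfg_doc["pool_size"],
            lstm_units=tuple(cfg_doc["lstm_units"]),
            fusion_units=cfg_doc["fusion_units"],
            dropout=cfg_doc["dropout"],
            learning_rate=cfg_doc["learning_rate"],
            batch_size=cfg_doc["batch_size"],
            epochs=cfg_doc["epochs"],
            class_weighting=cfg_doc["class_weighting"],
            seed=cfg_doc["seed"],
        )
        with np.load(npz_path) as data:
            state = {k: data[k] for k in data.files if not k.startswith("__")}
            body_scaler = _Scaler(data["__body_mean"], data["__body_std"])
            mouth_scaler = _Scaler(data["__mouth_mean"], data["__mouth_std"])
        net = TwoStreamNet(
            body_dim=meta["body_dim"],
            mouth_dim=meta["mouth_dim"],
            conv_blocks=cfg.conv_blocks,
            pool_size=cfg.pool_size,
            lstm_units=cfg.lstm_units,
            fusion_units=cfg.fusion_units,
            dropout=cfg.dropout,
            seed=cfg.seed,
        )
        net.load_state_dict(state)
        return cls(
            net=net,
            config=cfg,
            body_scaler=body_scaler,
            mouth_scaler=mouth_scaler,
            window_frames=meta["window_frames"],
            fps=meta["fps"],
            history=meta.get("history", {}),
        )


# ---------------------------------------------------------------------------
# clip construction and splitting
# ---------------------------------------------------------------------------

def extract_labeled_clips(
    features: TwoStreamFeatures,
    log: AnnotationLog,
    window_s: float = 2.0,
    negative_stride_s: float = 2.0,
    meal_id: str | None = None,
) -> ClipSet:
    """Cut labelled fixed-length windows out of one annotated meal.

    One positive clip is centred on each annotated bite (clips that would
    cross the meal boundary are dropped with a warning).  Negative clips
    are tiled every ``negative_stride_s`` over frames whose centre time is
    at least ``window_s`` away from every bite.
    """
    bites = log.bite_times()
    if len(bites) == 0:
        raise ValueError("annotation log contains no bites")
    n = features.n_frames
    fps = features.fps
    w = int(round(window_s * fps))
    if w > n:
        raise ValueError(f"window of {w} frames exceeds the meal ({n} frames)")
    half = w // 2

    meal = meal_id if meal_id is not None else (features.meal_id or "meal")
    starts: list[int] = []
    labels: list[int] = []

    dropped = 0
    for tb in bites:
        start = int(round(tb * fps)) - half
        if start < 0 or start + w > n:
            dropped += 1
            continue
        starts.append(start)
        labels.append(1)
    if dropped:
        warnings.warn(
            f"{meal}: dropped {dropped} positive clip(s) at the meal boundary",
            stacklevel=2,
        )

    step = max(1, int(round(negative_stride_s * fps)))
    for centre in range(half, n - w + half + 1, step):
        t_centre = centre / fps
        if np.min(np.abs(bites - t_centre)) >= window_s:
            starts.append(centre - half)
            labels.append(0)

    idx = np.asarray(starts)[:, None] + np.arange(w)[None, :]
    return ClipSet(
        body=features.body_stream[idx],
        mouth=features.mouth_stream[idx],
        labels=np.asarray(labels),
        provenance=tuple((meal, s) for s in starts),
        fps=fps,
    )


def split_clips(
    clips: ClipSet, train_fraction: float = 0.9, seed: int = 0
) -> tuple[ClipSet, ClipSet]:
    """Random stratified train/evaluation split.

    The evaluation set holds exactly ``floor((1 - train_fraction) * N)``
    clips, allocated across the labels proportionally (largest remainder),
    degenerating gracefully to a simple split if only one label is present.
    Deterministic in ``seed``.
    """
    if len(clips) < 2:
        raise ValueError("need at least two clips to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(clips)
    # tiny epsilon guards the floor against float error (0.1 * 10 -> 0.999...)
    n_eval = int(np.floor((1.0 - train_fraction) * n + 1e-9))

    labels = np.unique(clips.labels)
    quotas = {}
    remainders = []
    total = 0
    for lab in labels:
        exact = (clips.labels == lab).sum() * n_eval / n
        quotas[lab] = int(np.floor(exact))
        remainders.append((exact - quotas[lab], lab))
        total += quotas[lab]
    for _, lab in sorted(remainders, reverse=True)[: n_eval - total]:
        quotas[lab] += 1

    eval_idx: list[np.ndarray] = []
    for lab in labels:
        members = np.nonzero(clips.labels == lab)[0]
        members = rng.permutation(members)
        eval_idx.append(members[: quotas[lab]])
    eval_mask = np.zeros(n, dtype=bool)
    eval_mask[np.concatenate(eval_idx)] = True
    return clips.subset(np.nonzero(~eval_mask)[0]), clips.subset(np.nonzero(eval_mask)[0])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_model(train: ClipSet, cfg: ModelConfig | None = None) -> TrainedModel:
    """Train the two-stream classifier on labelled clips.

    Binary cross-entropy with optional class weighting (positive clips
    weighted by the observed non-bite/bite ratio), Adam optimization,
    shuffled mini-batches; fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or ModelConfig()
    labels = train.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both labels")

    body_scaler = _Scaler.fit(train.body)
    mouth_scaler = _Scaler.fit(train.mouth)
    xb = body_scaler(train.body)
    xm = mouth_scaler(train.mouth)
    y = labels.astype(float)

    weights = np.ones(len(y))
    if cfg.class_weighting:
        n_pos = labels.sum()
        n_neg = len(labels) - n_pos
        weights[labels == 1] = n_neg / n_pos

    ss = np.random.SeedSequence(cfg.seed)
    seed_net, seed_shuffle = ss.spawn(2)
    net = TwoStreamNet(
        body_dim=xb.shape[-1],
        mouth_dim=xm.shape[-1],
        conv_blocks=cfg.conv_blocks,
        pool_size=cfg.pool_size,
        lstm_units=cfg.lstm_units,
        fusion_units=cfg.fusion_units,
        dropout=cfg.dropout,
        seed=int(seed_net.generate_state(1)[0] % (2**31)),
    )
    opt = Adam(net, lr=cfg.learning_rate)
    rng = np.random.default_rng(seed_shuffle)

    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(len(y))
        losses = []
        correct = 0
        for s in range(0, len(y), cfg.batch_size):
            sel = order[s : s + cfg.batch_size]
            logits = net.forward(xb[sel], xm[sel], train=True)
            loss, dlogits = weighted_bce_with_logits(logits, y[sel], weights[sel])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int(((logits > 0) == (y[sel] > 0.5)).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / len(y))

    return TrainedModel(
        net=net,
        config=cfg,
        body_scaler=body_scaler,
        mouth_scaler=mouth_scaler,
        window_frames=train.window_frames,
        fps=train.fps,
        history=history,
    )


# ---------------------------------------------------------------------------
# inference and post-processing
# ---------------------------------------------------------------------------

def probability_signal(
    model: TrainedModel,
    features: TwoStreamFeatures,
    batch_size: int = 1024,
) -> ProbabilitySignal:
    """Slide the window over the whole meal with a step of one frame.

    Each window's probability is assigned to its centre frame; the leading
    and trailing frames that no window centre reaches are filled by
    replicating the nearest computed value, so the output has exactly one
    value per input frame.
    """
    n = features.n_frames
    w = model.window_frames
    if n < w:
        raise ValueError(f"meal ({n} frames) is shorter than the window ({w} frames)")
    half = w // 2
    n_windows = n - w + 1
    values = np.empty(n)
    probs = np.empty(n_windows)
    for s in range(0, n_windows, batch_size):
        e = min(s + batch_size, n_windows)
        idx = np.arange(s, e)[:, None] + np.arange(w)[None, :]
        probs[s:e] = model.predict_proba(
            features.body_stream[idx], features.mouth_stream[idx]
        )
    values[half : half + n_windows] = probs
    values[:half] = probs[0]
    values[half + n_windows :] = probs[-1]
    return ProbabilitySignal(values=values, fps=features.fps, meal_id=features.meal_id)


def local_maxima(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and heights of local maxima.

    A maximum is a maximal run of equal values strictly greater than both
    adjacent values.  Median filtering flattens peaks into short plateaus,
    so the run is anchored at its middle frame (the apex of a symmetric
    bump).  Runs touching the signal boundary do not count (no outside
    evidence).
    """
    n = len(x)
    idx = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if x[i] > x[i - 1] and j + 1 < n and x[i] > x[j + 1]:
            idx.append((i + j) // 2)
        i = j + 1
    idx_a = np.asarray(idx, dtype=int)
    return idx_a, x[idx_a]


def extract_bites(
    signal: ProbabilitySignal, cfg: PostprocessConfig | None = None
) -> AnnotationLog:
    """Convert the probability signal into detected bite events.

    Median-filter the signal, threshold at mean + k*SD of the filtered
    signal, take the local maxima strictly above the threshold, and prune
    maxima closer than ``min_separation_s`` by keeping the higher one
    (ties go to the earlier).  An empty result is allowed — a flat signal
    yields no bites since no value strictly exceeds its own mean.
    """
    cfg = cfg or PostprocessConfig()
    if len(signal.values) == 0:
        raise ValueError("empty probability signal")
    k = min(cfg.median_frames(signal.fps), len(signal.values) - (len(signal.values) + 1) % 2)
    # edge-replicating median keeps thresholding equivariant under positive
    # affine maps of the signal (zero padding would not)
    filt = median_filter(signal.values, size=max(1, k), mode="nearest")
    threshold = filt.mean() + cfg.threshold_k * filt.std()
    idx, heights = local_maxima(filt)
    above = heights > threshold
    idx, heights = idx[above], heights[above]

    min_gap = cfg.min_separation_s * signal.fps
    # greedy keep-highest: sort by (height desc, time asc), accept a maximum
    # only if no already-accepted one lies within min_gap frames
    order = np.lexsort((idx, -heights))
    accepted: list[int] = []
    for j in order:
        if all(abs(idx[j] - a) >= min_gap for a in accepted):
            accepted.append(int(idx[j]))
    accepted.sort()
    times = np.asarray(accepted, dtype=float) / signal.fps
    return AnnotationLog.from_events(
        [(float(t), "bite") for t in times], source="detected"
    )
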