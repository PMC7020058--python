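"""Synthetic meal generator: keypoint streams plus ground-truth event logs.

The generator emulates what a pose estimator produces from a side-view
(40-45 degree) recording of a seated eater at 25 fps, 720x576 px: a stream
of 8 upper-body joints and 4 mouth points.  Its kinematic model is minimal
but carries exactly the structure the detector relies on:

* Bite timings are drawn from a quadratic per-segment rate profile
  (expected bites per 10% of the meal), so meal-progress analytics can be
  validated against known generating coefficients.
* Each bite is a hand-to-mouth gesture: the dominant wrist travels from the
  plate anchor to a point next to the mouth and back with cubic
  ease-in/ease-out, peaking exactly at the (frame-aligned) bite time, while
  the mouth aperture (B-D distance) opens and closes in phase.
* Degradations mimic pose-estimator failure modes: Gaussian positional
  jitter, per-point dropout (missing detections) and one-frame outlier
  spikes to a uniform random in-frame position.
* The mouth corner away from the camera is rendered with low confidence so
  side selection has a ground truth.

All randomness derives from ``SimConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .keypoint_io import AnnotationLog, KeypointSequence

__all__ = [
    "SimConfig",
    "PosturePrototype",
    "DEFAULT_PROTOTYPE",
    "DEFAULT_RATE_PROFILE",
    "simulate_bite_times",
    "simulate_meal",
    "InvalidProfileError",
    "OverlappingGestureError",
]

#: Per-segment expected bite counts y0 + a*x + b*x^2, x = 1..10 — the
#: manually annotated hash-meal curve used as the generator's default.
DEFAULT_RATE_PROFILE: tuple[float, float, float] = (6.909, -0.7409, 0.0683)


class InvalidProfileError(ValueError):
    """Rate profile yields a negative expected count in some segment."""


class OverlappingGestureError(ValueError):
    """Gesture duration is not shorter than the smallest inter-bite gap."""


@dataclass
class SimConfig:
    """Study conditions for one simulated meal.

    duration_s : meal length in seconds.
    fps : video frame rate (25 matches the recordings this emulates).
    frame_size : (width, height) in pixels.
    rate_profile : (y0, a, b) of expected bites per 10% segment.
    gesture_duration_s : full plate->mouth->plate reach time.
    spoonful_lead_s : spoonful annotation precedes each bite by this much.
    jitter_px : SD of Gaussian positional noise per coordinate per frame.
    dropout_prob : per-point per-frame probability of a missing detection.
    outlier_prob : per-point per-frame probability of a one-frame spike.
    refractory_s : minimum separation enforced between consecutive bites.
    visible_side : which mouth corner faces the camera ("left" or "right").
    seed : seeds every random draw of the simulation.
    """

    duration_s: float = 480.0
    fps: float = 25.0
    frame_size: tuple[int, int] = (720, 576)
    rate_profile: tuple[float, float, float] = DEFAULT_RATE_PROFILE
    gesture_duration_s: float = 1.0
    spoonful_lead_s: float = 0.5
    jitter_px: float = 1.5
    dropout_prob: float = 0.02
    outlier_prob: float = 0.005
    refractory_s: float = 1.5
    visible_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        for name in ("dropout_prob", "outlier_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be non-negative")
        if self.visible_side not in ("left", "right"):
            raise ValueError("visible_side must be 'left' or 'right'")


@dataclass
class PosturePrototype:
    """Rest posture of the eater plus the two gesture anchors.

    ``body_rest``/``mouth_rest`` give the at-rest position of each of the
    8 joints and 4 mouth points; ``plate_anchor`` is where the dominant
    wrist rests between bites, ``mouth_anchor`` where it peaks during one.
    """

    body_rest: np.ndarray
    mouth_rest: np.ndarray
    plate_anchor: np.ndarray
    mouth_anchor: np.ndarray
    dominant_arm: tuple[int, int, int] = (5, 6, 7)  # shoulder, elbow, wrist

    def __post_init__(self) -> None:
        self.body_rest = np.asarray(self.body_rest, dtype=float)
        self.mouth_rest = np.asarray(self.mouth_rest, dtype=float)
        self.plate_anchor = np.asarray(self.plate_anchor, dtype=float)
        self.mouth_anchor = np.asarray(self.mouth_anchor, dtype=float)
        if self.body_rest.shape != (8, 2) or self.mouth_rest.shape != (4, 2):
            raise ValueError("body_rest must be (8, 2), mouth_rest (4, 2)")
        nose = self.body_rest[0]
        if np.any(np.linalg.norm(self.mouth_rest - nose, axis=1) > 80):
            raise ValueError("mouth points must lie near the nose")

    def validate_bounds(self, frame_size: tuple[int, int]) -> None:
        w, h = frame_size
        pts = np.vstack(
            [self.body_rest, self.mouth_rest, self.plate_anchor, self.mouth_anchor]
        )
        if np.any(pts < 0) or np.any(pts[:, 0] > w) or np.any(pts[:, 1] > h):
            raise ValueError("prototype positions must lie inside the frame")


DEFAULT_PROTOTYPE = PosturePrototype(
    body_rest=np.array(
        [
            [360.0, 150.0],  # 0 nose
            [360.0, 225.0],  # 1 neck
            [300.0, 235.0],  # 2 r_shoulder (away from camera)
            [282.0, 330.0],  # 3 r_elbow
            [296.0, 410.0],  # 4 r_wrist
            [420.0, 235.0],  # 5 l_shoulder (camera side)
            [442.0, 330.0],  # 6 l_elbow
            [430.0, 430.0],  # 7 l_wrist = eating hand
        ]
    ),
    mouth_rest=np.array(
        [
            [346.0, 185.0],  # A left corner
            [360.0, 179.0],  # B upper-lip middle
            [374.0, 185.0],  # C right corner
            [360.0, 187.0],  # D lower-lip middle
        ]
    ),
    plate_anchor=np.array([430.0, 430.0]),
    mouth_anchor=np.array([368.0, 194.0]),
)


def _segment_rates(profile: Sequence[float], n_segments: int = 10) -> np.ndarray:
    y0, a, b = (float(v) for v in profile)
    x = np.arange(1, n_segments + 1, dtype=float)
    rates = y0 + a * x + b * x * x
    if np.any(rates < 0):
        bad = int(x[rates < 0][0])
        raise InvalidProfileError(
            f"rate profile gives a negative expected count at segment {bad}"
        )
    return rates


def simulate_bite_times(
    duration_s: float,
    rate_profile: Sequence[float] = DEFAULT_RATE_PROFILE,
    seed: int | None = 0,
    refractory_s: float = 1.5,
    rng: np.random.Generator | None = None,
    max_redraws: int = 1000,
) -> np.ndarray:
    """Draw bite timestamps from a quadratic per-segment rate profile.

    Sampling recipe (all draws from ``numpy.random.default_rng(seed)`` in
    this exact order):

    1. For segment ``i = 1..10`` covering a tenth of ``duration_s``, draw a
       Poisson count with mean ``y0 + a*i + b*i**2``, then that many
       positions uniformly inside the segment.
    2. Sort all positions.  While any consecutive gap is below
       ``refractory_s``: the later bite of the first offending pair is
       re-drawn uniformly within its own segment and the list re-sorted.
       After ``max_redraws`` re-draws that bite is dropped instead.

    Re-drawing positions (rather than rejecting whole placements) keeps the
    per-segment counts exactly Poisson with the profile's means.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    rates = _segment_rates(rate_profile)
    if rng is None:
        rng = np.random.default_rng(seed)
    seg_len = duration_s / 10.0

    times: list[float] = []
    segs: list[int] = []
    for i in range(10):
        n = int(rng.poisson(rates[i]))
        pos = i * seg_len + rng.uniform(0.0, seg_len, size=n)
        times.extend(pos.tolist())
        segs.extend([i] * n)

    times_a = np.array(times)
    segs_a = np.array(segs, dtype=int)
    order = np.argsort(times_a, kind="stable")
    times_a, segs_a = times_a[order], segs_a[order]

    redraws = 0
    while len(times_a) > 1:
        gaps = np.diff(times_a)
        bad = np.nonzero(gaps < refractory_s)[0]
        if len(bad) == 0:
            break
        j = int(bad[0]) + 1  # the later bite of the first offending pair
        if redraws >= max_redraws:
            times_a = np.delete(times_a, j)
            segs_a = np.delete(segs_a, j)
            redraws = 0
            continue
        seg = segs_a[j]
        times_a[j] = seg * seg_len + rng.uniform(0.0, seg_len)
        order = np.argsort(times_a, kind="stable")
        times_a, segs_a = times_a[order], segs_a[order]
        redraws += 1
    return np.sort(times_a)


def _ease_bump(u: np.ndarray) -> np.ndarray:
    """Cubic ease-in/ease-out bump on [0, 1]: 0 at the ends, 1 at u=0.5."""
    u = np.clip(u, 0.0, 1.0)
    s = np.where(u <= 0.5, 2.0 * u, 2.0 * (1.0 - u))
    return 3.0 * s**2 - 2.0 * s**3


def simulate_meal(
    config: SimConfig, prototype: PosturePrototype | None = None
) -> tuple[KeypointSequence, AnnotationLog]:
    """Render one meal as a keypoint sequence plus its ground-truth log.

    Bite times are drawn by :func:`simulate_bite_times` and snapped to the
    frame grid, so the annotated bite frame is exactly the frame of closest
    wrist-to-mouth approach and of peak mouth aperture in the noise-free
    kinematics.  The log contains one spoonful ``spoonful_lead_s`` before
    each bite, a ``meal_start`` at the first spoonful and ``meal_stop`` at
    the last bite.
    """
    proto = DEFAULT_PROTOTYPE if prototype is None else prototype
    proto.validate_bounds(config.frame_size)

    ss = np.random.SeedSequence(config.seed)
    rng_times, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    bite_times = simulate_bite_times(
        config.duration_s,
        config.rate_profile,
        refractory_s=config.refractory_s,
        rng=rng_times,
    )
    n_frames = int(round(config.duration_s * config.fps))
    # snap to the frame grid (and inside the meal)
    bite_frames = np.unique(
        np.clip(np.round(bite_times * config.fps).astype(int), 0, n_frames - 1)
    )
    bite_times = bite_frames / config.fps

    if len(bite_times) > 1:
        min_gap = float(np.min(np.diff(bite_times)))
        if config.gesture_duration_s >= min_gap:
            raise OverlappingGestureError(
                f"gesture_duration_s={config.gesture_duration_s} is not below the "
                f"minimum inter-bite gap ({min_gap:.3f} s); gestures would overlap"
            )

    t = np.arange(n_frames) / config.fps
    body = np.tile(proto.body_rest, (n_frames, 1, 1))
    mouth = np.tile(proto.mouth_rest, (n_frames, 1, 1))

    # slow whole-body sway: a rigid translation of every point, so relative
    # geometry (and hence the features) is unaffected
    phase = rng_noise.uniform(0.0, 2.0 * np.pi)
    sway = 2.0 * np.column_stack(
        [np.sin(2.0 * np.pi * 0.08 * t + phase), 0.5 * np.cos(2.0 * np.pi * 0.05 * t + phase)]
    )

    sh, el, wr = proto.dominant_arm
    g = config.gesture_duration_s
    reach = proto.mouth_anchor - proto.plate_anchor
    aperture_amp = 14.0
    for tb in bite_times:
        u = (t - (tb - g / 2.0)) / g
        inside = (u >= 0.0) & (u <= 1.0)
        if not np.any(inside):
            continue
        w = _ease_bump(u[inside])
        body[inside, wr, :] = proto.plate_anchor + w[:, None] * reach
        body[inside, el, :] += 0.4 * w[:, None] * reach
        # mouth opens in phase with the reach: lower lip drops, upper lifts
        mouth[inside, 3, 1] += 0.75 * aperture_amp * w
        mouth[inside, 1, 1] -= 0.25 * aperture_amp * w

    body += sway[:, None, :]
    mouth += sway[:, None, :]

    # --- confidences -------------------------------------------------------
    conf_b = np.clip(rng_noise.normal(0.9, 0.05, size=(n_frames, 8)), 0.5, 1.0)
    conf_m = np.clip(rng_noise.normal(0.9, 0.05, size=(n_frames, 4)), 0.5, 1.0)
    hidden_corner = 2 if config.visible_side == "left" else 0  # C hides if left visible
    conf_m[:, hidden_corner] = np.clip(
        rng_noise.normal(0.35, 0.05, size=n_frames), 0.05, 0.5
    )

    # --- degradations ------------------------------------------------------
    w_px, h_px = config.frame_size
    pts = np.concatenate([body, mouth], axis=1)  # (n, 12, 2)
    conf = np.concatenate([conf_b, conf_m], axis=1)  # (n, 12)
    if config.jitter_px > 0:
        pts = pts + rng_noise.normal(0.0, config.jitter_px, size=pts.shape)
    spike = rng_noise.random(size=(n_frames, 12)) < config.outlier_prob
    if spike.any():
        n_spk = int(spike.sum())
        pts[spike] = np.column_stack(
            [rng_noise.uniform(0, w_px, n_spk), rng_noise.uniform(0, h_px, n_spk)]
        )
    drop = rng_noise.random(size=(n_frames, 12)) < config.dropout_prob
    pts[drop] = np.nan
    conf = np.where(drop, 0.0, conf)

    seq = KeypointSequence(
        body=np.dstack([pts[:, :8], conf[:, :8, None]]),
        mouth=np.dstack([pts[:, 8:], conf[:, 8:, None]]),
        fps=config.fps,
        frame_size=config.frame_size,
        meta=f"synth(seed={config.seed})",
    )

    events: list[tuple[float, str]] = [(float(tb), "bite") for tb in bite_times]
    for tb in bite_times:
        events.append((float(max(0.0, tb - config.spoonful_lead_s)), "spoonful"))
    if events:
        first_spoonful = min(tt for tt, k in events if k == "spoonful")
        events.append((first_spoonful, "meal_start"))
        events.append((float(bite_times[-1]), "meal_stop"))
    log = AnnotationLog.from_events(events, source="manual")
    return seq, log
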