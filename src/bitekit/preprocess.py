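"""Cleaning, smoothing and feature assembly for keypoint streams.

The raw pose-estimator output is degraded by missing detections, low
confidence points and one-frame spikes.  The pipeline here is:

1. :func:`clean_sequence` — mark low-confidence points and one-frame
   outlier jumps as missing, then fill every missing value with the value
   of the previous frame (leading gaps back-filled from the first valid
   frame).
2. :func:`smooth_sequence` — replace each coordinate trajectory with a
   smoothing-spline evaluation at every frame.
3. :func:`select_mouth_side` — pick the mouth corner (A=left, C=right)
   that the camera actually sees, by mean detection confidence.
4. :func:`assemble_features` — build the two feature streams the
   classifier consumes: upper-body joints in neck-origin coordinates plus
   all pairwise inter-joint distances, and mouth points (B, D and the
   selected corner) in nose-origin coordinates plus their pairwise
   distances.

Features are translation invariant by construction and stay in pixel
units; an optional per-meal z-scoring switch exists but is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline, make_smoothing_spline

from .keypoint_io import BODY_JOINTS, MOUTH_POINTS, KeypointSequence

__all__ = [
    "CleaningConfig",
    "TwoStreamFeatures",
    "clean_sequence",
    "smooth_sequence",
    "select_mouth_side",
    "assemble_features",
    "UnrecoverablePointError",
    "BODY_FEATURE_NAMES",
    "MOUTH_FEATURE_NAMES",
]

_POINT_NAMES = [*BODY_JOINTS, *(f"mouth_{m}" for m in MOUTH_POINTS)]

BODY_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(8) for j in range(i + 1, 8)
)  # 28 pairs, lexicographic

BODY_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{BODY_JOINTS[i]}_{ax}" for i in range(8) for ax in ("x", "y")
) + tuple(f"d_{BODY_JOINTS[i]}_{BODY_JOINTS[j]}" for i, j in BODY_PAIRS)

MOUTH_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{p}_{ax}" for p in ("B", "D", "corner") for ax in ("x", "y")
) + ("d_B_D", "d_B_corner", "d_D_corner")


class UnrecoverablePointError(ValueError):
    """A point was never detected over the whole sequence."""


_LAMBDA_GRID = np.logspace(-6, 6, 13)


def _cv_spline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cubic smoothing spline with a cross-validated smoothing parameter.

    Short trajectories (<= 600 samples) use generalized cross-validation
    directly.  Longer ones select the penalty on a decimated grid — fit
    every ``stride``-th sample for each candidate penalty, score on the
    skipped samples, rescale the winner by ``stride`` (the residual term
    grows with the sample count at a fixed span) — and then fit the full
    trajectory once.  This keeps the selection cost roughly constant per
    trajectory regardless of meal length.
    """
    n = len(x)
    if n <= 600:
        return make_smoothing_spline(x, y)(x)
    stride = int(np.ceil(n / 600))
    xs, ys = x[::stride], y[::stride]
    off = stride // 2
    xv, yv = x[off::stride], y[off::stride]
    best_lam, best_err = None, np.inf
    for lam in _LAMBDA_GRID:
        fit = make_smoothing_spline(xs, ys, lam=lam)
        err = float(np.mean((fit(xv) - yv) ** 2))
        if err < best_err:
            best_lam, best_err = lam, err
    return make_smoothing_spline(x, y, lam=best_lam * stride)(x)


@dataclass
class CleaningConfig:
    """Parameters of the cleaning and smoothing stages.

    confidence_floor : detections below this confidence are discarded.
    jump_fraction : one-frame displacement above this fraction of the frame
        diagonal is treated as an outlier spike.
    spline_smoothing : per-frame smoothing budget; 0 gives an interpolating
        spline, ``None`` selects the factor by generalized cross-validation
        (cubic only).
    spline_degree : spline degree (default cubic).
    zscore : per-meal feature standardization switch (off by default; the
        location normalization alone matches how the features are defined).
    """

    confidence_floor: float = 0.1
    jump_fraction: float = 0.15
    spline_smoothing: float | None = None
    spline_degree: int = 3
    zscore: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.confidence_floor <= 1:
            raise ValueError("confidence_floor must be in [0, 1]")
        if not self.jump_fraction > 0:
            raise ValueError("jump_fraction must be positive")
        if self.spline_smoothing is not None and self.spline_smoothing < 0:
            raise ValueError("spline_smoothing must be non-negative")


@dataclass
class TwoStreamFeatures:
    """Per-frame feature matrices for the body and mouth streams.

    ``body_stream`` is (n_frames, 44): the 8 joints' (x, y) relative to the
    neck (16 values, neck itself identically zero) followed by the 28
    pairwise inter-joint distances in lexicographic pair order.
    ``mouth_stream`` is (n_frames, 9): (x, y) of B, D and the selected
    corner relative to the nose, then distances d(B,D), d(B,corner),
    d(D,corner).  Layouts are spelled out in ``BODY_FEATURE_NAMES`` and
    ``MOUTH_FEATURE_NAMES``.
    """

    body_stream: np.ndarray
    mouth_stream: np.ndarray
    fps: float
    side: str
    meal_id: str = ""

    def __post_init__(self) -> None:
        self.body_stream = np.asarray(self.body_stream, dtype=float)
        self.mouth_stream = np.asarray(self.mouth_stream, dtype=float)
        if self.body_stream.shape[1] != len(BODY_FEATURE_NAMES):
            raise ValueError("body_stream has wrong width")
        if self.mouth_stream.shape[1] != len(MOUTH_FEATURE_NAMES):
            raise ValueError("mouth_stream has wrong width")
        if self.body_stream.shape[0] != self.mouth_stream.shape[0]:
            raise ValueError("stream lengths differ")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def n_frames(self) -> int:
        return self.body_stream.shape[0]


def _clean_trajectory(
    xy: np.ndarray, conf: np.ndarray, floor: float, jump_px: float, name: str
) -> tuple[np.ndarray, np.ndarray]:
    """Clean one point's trajectory; returns filled (n, 2) coords and conf."""
    n = xy.shape[0]
    missing = (conf < floor) | ~np.isfinite(xy).all(axis=1)
    valid_idx = np.nonzero(~missing)[0]
    if len(valid_idx) == 0:
        raise UnrecoverablePointError(f"point {name!r} was never detected")

    # one-frame spike rule over the valid samples: flag a sample if it jumps
    # more than jump_px away from the last accepted value AND the next valid
    # sample returns to within jump_px of that accepted value (a sustained
    # move is kept).  A final valid sample with no successor is flagged on
    # the jump alone.
    keep = np.ones(len(valid_idx), dtype=bool)
    last_good = xy[valid_idx[0]]
    for k in range(1, len(valid_idx)):
        cur = xy[valid_idx[k]]
        if np.linalg.norm(cur - last_good) > jump_px:
            if k + 1 < len(valid_idx):
                nxt = xy[valid_idx[k + 1]]
                if np.linalg.norm(nxt - last_good) <= jump_px:
                    keep[k] = False
                    continue
            else:
                keep[k] = False
                continue
        last_good = cur
    missing = missing.copy()
    missing[valid_idx[~keep]] = True

    out_xy = xy.copy()
    out_conf = conf.copy()
    good = np.nonzero(~missing)[0]
    if len(good) == 0:  # every survivor was a spike; fall back to raw valids
        good = valid_idx
        missing = np.ones(n, dtype=bool)
        missing[good] = False
    # forward fill from the previous valid frame; leading gap back-filled
    src = np.maximum.accumulate(np.where(~missing, np.arange(n), -1))
    src[src < 0] = good[0]
    out_xy[:] = xy[src]
    out_conf[:] = conf[src]
    return out_xy, out_conf


def clean_sequence(seq: KeypointSequence, cfg: CleaningConfig | None = None) -> KeypointSequence:
    """Remove low-confidence and spiking points, then fill gaps.

    Points with confidence below ``cfg.confidence_floor`` or making a
    one-frame jump larger than ``cfg.jump_fraction`` of the frame diagonal
    are marked missing; every missing value is then replaced by the value
    of the previous frame (leading gaps back-filled from the first valid
    frame).  The output has no missing values provided every point was
    detected at least once; otherwise :class:`UnrecoverablePointError`
    names the offending point.  Applying the operation twice equals once.
    """
    if seq.n_frames == 0:
        raise ValueError("empty sequence")
    cfg = cfg or CleaningConfig()
    diag = float(np.hypot(*seq.frame_size))
    jump_px = cfg.jump_fraction * diag
    pts = seq.points().copy()
    for p in range(12):
        xy, conf = _clean_trajectory(
            pts[:, p, :2], pts[:, p, 2], cfg.confidence_floor, jump_px, _POINT_NAMES[p]
        )
        pts[:, p, :2] = xy
        pts[:, p, 2] = conf
    out = seq.copy()
    out.body = pts[:, :8]
    out.mouth = pts[:, 8:]
    return out


def smooth_sequence(seq: KeypointSequence, cfg: CleaningConfig | None = None) -> KeypointSequence:
    """Replace each coordinate trajectory with a smoothing-spline fit.

    With ``spline_smoothing=0`` the spline interpolates and the output
    equals the input at every frame; with ``None`` the smoothing parameter
    is chosen per trajectory by generalized cross-validation.  Requires a
    cleaned (gap-free) sequence and at least ``spline_degree + 1`` frames.
    """
    cfg = cfg or CleaningConfig()
    n = seq.n_frames
    if n < cfg.spline_degree + 1:
        raise ValueError(
            f"need at least spline_degree + 1 = {cfg.spline_degree + 1} frames, got {n}"
        )
    pts = seq.points()
    if not np.isfinite(pts[:, :, :2]).all():
        raise ValueError("sequence has missing values; run clean_sequence first")
    x = np.arange(n, dtype=float)
    out = pts.copy()
    for p in range(12):
        for ax in range(2):
            y = pts[:, p, ax]
            if cfg.spline_smoothing is None:
                if cfg.spline_degree != 3:
                    raise ValueError("CV-selected smoothing is cubic only")
                out[:, p, ax] = _cv_spline(x, y)
            elif cfg.spline_smoothing == 0:
                out[:, p, ax] = y
            else:
                spl = UnivariateSpline(
                    x, y, k=cfg.spline_degree, s=cfg.spline_smoothing * n
                )
                out[:, p, ax] = spl(x)
    res = seq.copy()
    res.body = out[:, :8]
    res.mouth = out[:, 8:]
    return res


def select_mouth_side(seq: KeypointSequence) -> str:
    """Pick the visible mouth corner by mean detection confidence.

    Returns ``"left"`` (corner A) or ``"right"`` (corner C); ties go left.
    Missing detections count as confidence 0.
    """
    conf = np.nan_to_num(seq.mouth[:, :, 2], nan=0.0)
    mean_a = float(conf[:, 0].mean())
    mean_c = float(conf[:, 2].mean())
    if mean_a == 0.0 and mean_c == 0.0:
        raise ValueError("neither mouth corner was ever detected")
    return "left" if mean_a >= mean_c else "right"


def _pairwise_distances(coords: np.ndarray, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.stack(
        [np.linalg.norm(coords[:, i] - coords[:, j], axis=1) for i, j in pairs], axis=1
    )


def assemble_features(
    seq: KeypointSequence, side: str, zscore: bool = False, meal_id: str = ""
) -> TwoStreamFeatures:
    """Build the two classifier input streams from a cleaned sequence.

    Body stream: joints 0-7 in neck-origin coordinates plus all 28 pairwise
    inter-joint distances.  Mouth stream: B, D and the side's corner in
    nose-origin coordinates plus their 3 pairwise distances.  Exactly
    invariant to global translation of the raw keypoints.
    """
    pts = seq.points()
    if not np.isfinite(pts[:, :, :2]).all():
        raise ValueError("sequence has missing values; run clean_sequence first")
    body_xy = seq.body[:, :, :2]
    neck = body_xy[:, 1:2, :]
    body_rel = (body_xy - neck).reshape(seq.n_frames, 16)
    body_dist = _pairwise_distances(body_xy, BODY_PAIRS)
    body_stream = np.concatenate([body_rel, body_dist], axis=1)

    corner = 0 if side == "left" else 2  # A or C
    mouth_sel = seq.mouth[:, [1, 3, corner], :2]  # B, D, corner
    nose = body_xy[:, 0:1, :]
    mouth_rel = (mouth_sel - nose).reshape(seq.n_frames, 6)
    mouth_dist = _pairwise_distances(mouth_sel, [(0, 1), (0, 2), (1, 2)])
    mouth_stream = np.concatenate([mouth_rel, mouth_dist], axis=1)

    if zscore:
        for arr in (body_stream, mouth_stream):
            sd = arr.std(axis=0)
            sd[sd == 0] = 1.0
            arr -= arr.mean(axis=0)
            arr /= sd
    return TwoStreamFeatures(
        body_stream=body_stream,
        mouth_stream=mouth_stream,
        fps=seq.fps,
        side=side,
        meal_id=meal_id,
    )
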