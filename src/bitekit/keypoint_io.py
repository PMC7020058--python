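"""Keypoint streams, annotation logs and their on-disk dialects.

Conventions used throughout the package
---------------------------------------
* Coordinates are pixels, origin at the top-left of the frame, y increasing
  downward.  Times are seconds; frames are 0-based; the time of frame ``i``
  is ``i / fps``.
* Eight upper-body joints are tracked, numbered as in common pose-estimator
  output: 0 nose, 1 neck, 2-4 right shoulder/elbow/wrist, 5-7 left
  shoulder/elbow/wrist.  Four mouth points are tracked: A left corner,
  B upper-lip middle, C right corner, D lower-lip middle.  When mapping
  from a 70-point face layout the indices are A=48, B=51, C=54, D=57.
* A missing point is encoded explicitly as confidence 0 with NaN
  coordinates — never as a silent (0, 0).

Two keypoint dialects are supported:

``json_frames``
    One JSON document per meal: top-level ``fps``, ``frame_size``, ``meta``
    and a ``frames`` array; each frame is an object with ``body``
    (8 x [x, y, c]) and ``mouth`` (4 x [x, y, c]) arrays.  A constrained
    subset of per-frame pose-estimator JSON output.

``csv_flat``
    A flat CSV with columns ``frame, point_name, x, y, confidence`` preceded
    by ``# fps=...`` / ``# frame_size=WxH`` / ``# meta=...`` header lines.

Annotation logs are CSVs with columns ``time_s, event`` where ``event`` is
one of ``meal_start, meal_stop, spoonful, food_addition, bite``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BODY_JOINTS",
    "MOUTH_POINTS",
    "EVENT_KINDS",
    "KeypointSequence",
    "AnnotationLog",
    "read_keypoints",
    "write_keypoints",
    "read_annotations",
    "write_annotations",
    "write_behavior_log",
    "KeypointIOError",
    "SchemaError",
]

BODY_JOINTS: tuple[str, ...] = (
    "nose",
    "neck",
    "r_shoulder",
    "r_elbow",
    "r_wrist",
    "l_shoulder",
    "l_elbow",
    "l_wrist",
)
MOUTH_POINTS: tuple[str, ...] = ("A", "B", "C", "D")
EVENT_KINDS: frozenset[str] = frozenset(
    {"meal_start", "meal_stop", "spoonful", "food_addition", "bite"}
)

# event times use fixed decimal rendering (frame-aligned times survive it
# exactly); keypoint coordinates are written at full precision so a
# write->read round trip reproduces the sequence bit for bit
_TIME_FMT = "%.6f"


class KeypointIOError(ValueError):
    """Malformed keypoint or annotation file."""


class SchemaError(KeypointIOError):
    """File structure does not match the documented dialect."""


def _as_point_array(arr, n_points: int, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim != 3 or out.shape[1:] != (n_points, 3):
        raise SchemaError(
            f"{name} array must have shape (n_frames, {n_points}, 3); got {out.shape}"
        )
    return out


@dataclass
class KeypointSequence:
    """Per-frame 2-D keypoints with confidences for one meal.

    Attributes
    ----------
    body : (n_frames, 8, 3) array of x, y, confidence.
    mouth : (n_frames, 4, 3) array of x, y, confidence.
    fps : frames per second (> 0).
    frame_size : (width, height) in pixels.
    meta : free-text source identifier.
    """

    body: np.ndarray
    mouth: np.ndarray
    fps: float
    frame_size: tuple[int, int] = (720, 576)
    meta: str = ""

    def __post_init__(self) -> None:
        self.body = _as_point_array(self.body, 8, "body")
        self.mouth = _as_point_array(self.mouth, 4, "mouth")
        if self.body.shape[0] != self.mouth.shape[0]:
            raise SchemaError("body and mouth frame counts differ")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        self.frame_size = (int(self.frame_size[0]), int(self.frame_size[1]))

    @property
    def n_frames(self) -> int:
        return self.body.shape[0]

    def times(self) -> np.ndarray:
        """Frame times in seconds, exactly ``i / fps``."""
        return np.arange(self.n_frames) / self.fps

    def points(self) -> np.ndarray:
        """All 12 points stacked, shape (n_frames, 12, 3); body first."""
        return np.concatenate([self.body, self.mouth], axis=1)

    def missing_mask(self) -> np.ndarray:
        """(n_frames, 12) bool mask of missing points."""
        pts = self.points()
        return (pts[:, :, 2] <= 0) | ~np.isfinite(pts[:, :, 0]) | ~np.isfinite(pts[:, :, 1])

    def out_of_bounds_mask(self) -> np.ndarray:
        """(n_frames, 12) bool mask of present points outside the frame."""
        pts = self.points()
        w, h = self.frame_size
        with np.errstate(invalid="ignore"):
            oob = (pts[:, :, 0] < 0) | (pts[:, :, 0] > w) | (pts[:, :, 1] < 0) | (pts[:, :, 1] > h)
        return oob & ~self.missing_mask()

    def copy(self) -> "KeypointSequence":
        return replace(self, body=self.body.copy(), mouth=self.mouth.copy())

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, KeypointSequence):
            return NotImplemented
        return (
            self.fps == other.fps
            and self.frame_size == other.frame_size
            and self.meta == other.meta
            and np.array_equal(self.body, other.body, equal_nan=True)
            and np.array_equal(self.mouth, other.mouth, equal_nan=True)
        )


@dataclass
class AnnotationLog:
    """Timestamped behavioural events for one meal.

    Five event kinds are recognised: ``meal_start`` (time of the initial
    spoonful), ``meal_stop`` (time of the last bite), ``spoonful`` (food
    leaves the personal plate), ``food_addition`` (food moved from serving
    tray to plate) and ``bite`` (food enters the mouth).
    """

    times: np.ndarray
    kinds: tuple[str, ...]
    source: str = "manual"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.kinds = tuple(self.kinds)
        if self.times.shape != (len(self.kinds),):
            raise ValueError("times and kinds lengths differ")
        unknown = set(self.kinds) - EVENT_KINDS
        if unknown:
            raise KeypointIOError(f"unknown event kind(s): {sorted(unknown)}")
        if np.any(self.times < 0):
            raise KeypointIOError("negative event time")
        if self.source not in ("manual", "detected"):
            raise ValueError("source must be 'manual' or 'detected'")
        if np.any(np.diff(self.times) < 0):
            raise KeypointIOError("event times must be non-decreasing")
        for kind in ("meal_start", "meal_stop"):
            if self.kinds.count(kind) > 1:
                raise KeypointIOError(f"more than one {kind} event")

    @classmethod
    def from_events(
        cls, events: Iterable[tuple[float, str]], source: str = "manual", sort: bool = True
    ) -> "AnnotationLog":
        ev = list(events)
        times = np.array([t for t, _ in ev], dtype=float)
        kinds = [k for _, k in ev]
        if sort and np.any(np.diff(times) < 0):
            order = np.argsort(times, kind="stable")
            times = times[order]
            kinds = [kinds[i] for i in order]
        return cls(times=times, kinds=tuple(kinds), source=source)

    @property
    def n_events(self) -> int:
        return len(self.kinds)

    def bite_times(self) -> np.ndarray:
        return self.times[[k == "bite" for k in self.kinds]]

    def of_kind(self, kind: str) -> np.ndarray:
        return self.times[[k == kind for k in self.kinds]]

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, AnnotationLog):
            return NotImplemented
        return (
            self.source == other.source
            and self.kinds == other.kinds
            and np.array_equal(self.times, other.times)
        )


# ---------------------------------------------------------------------------
# keypoint dialects
# ---------------------------------------------------------------------------

def _cell(v: float):
    return None if not np.isfinite(v) else float(v)


def write_keypoints(seq: KeypointSequence, path, dialect: str = "json_frames") -> None:
    """Write a keypoint sequence in the given dialect (see module docstring)."""
    path = Path(path)
    if dialect == "json_frames":
        frames = []
        for i in range(seq.n_frames):
            frames.append(
                {
                    "body": [[_cell(x), _cell(y), _cell(c)] for x, y, c in seq.body[i]],
                    "mouth": [[_cell(x), _cell(y), _cell(c)] for x, y, c in seq.mouth[i]],
                }
            )
        doc = {
            "fps": seq.fps,
            "frame_size": list(seq.frame_size),
            "meta": seq.meta,
            "frames": frames,
        }
        path.write_text(json.dumps(doc, separators=(",", ":")) + "\n")
    elif dialect == "csv_flat":
        names = [*BODY_JOINTS, *(f"mouth_{m}" for m in MOUTH_POINTS)]
        pts = seq.points()
        n = seq.n_frames
        rows = {
            "frame": np.repeat(np.arange(n), 12),
            "point_name": np.tile(np.array(names, dtype=object), n),
            "x": pts[:, :, 0].ravel(),
            "y": pts[:, :, 1].ravel(),
            "confidence": pts[:, :, 2].ravel(),
        }
        df = pd.DataFrame(rows)
        with path.open("w") as fh:
            fh.write(f"# fps={seq.fps:g}\n")
            fh.write(f"# frame_size={seq.frame_size[0]}x{seq.frame_size[1]}\n")
            fh.write(f"# meta={seq.meta}\n")
            df.to_csv(fh, index=False, na_rep="")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _load_json_frames(path: Path) -> KeypointSequence:
    doc = json.loads(path.read_text())
    for key in ("fps", "frames"):
        if key not in doc:
            raise SchemaError(f"missing required top-level key {key!r}")
    if "frame_size" not in doc:
        raise SchemaError("missing frame_size metadata")
    n = len(doc["frames"])
    body = np.full((n, 8, 3), np.nan)
    mouth = np.full((n, 4, 3), np.nan)
    for i, fr in enumerate(doc["frames"]):
        for key, arr, npts in (("body", body, 8), ("mouth", mouth, 4)):
            pts = fr.get(key)
            if pts is None or len(pts) != npts:
                raise SchemaError(
                    f"frame {i}: expected {npts} {key} points, got "
                    f"{'none' if pts is None else len(pts)}"
                )
            for j, xyz in enumerate(pts):
                if len(xyz) != 3:
                    raise SchemaError(f"frame {i}: {key} point {j} is not [x, y, c]")
                arr[i, j] = [np.nan if v is None else float(v) for v in xyz]
    seq = KeypointSequence(
        body=body,
        mouth=mouth,
        fps=float(doc["fps"]),
        frame_size=tuple(doc["frame_size"]),
        meta=str(doc.get("meta", "")),
    )
    _normalise_missing(seq)
    return seq


def _load_csv_flat(path: Path) -> KeypointSequence:
    header: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    if "fps" not in header:
        raise SchemaError("missing fps metadata in csv_flat header")
    if "frame_size" not in header:
        raise SchemaError("missing frame_size metadata in csv_flat header")
    w, _, h = header["frame_size"].partition("x")
    required = {"frame", "point_name", "x", "y", "confidence"}
    if not required.issubset(df.columns):
        raise SchemaError(f"csv_flat requires columns {sorted(required)}")

    names = [*BODY_JOINTS, *(f"mouth_{m}" for m in MOUTH_POINTS)]
    name_idx = {nm: i for i, nm in enumerate(names)}
    bad = set(df["point_name"]) - set(names)
    if bad:
        raise SchemaError(f"unknown point name(s): {sorted(bad)}")

    frames = df["frame"].to_numpy()
    if np.any(np.diff(frames) < 0):
        raise SchemaError("frame indices are not non-decreasing")
    n = int(frames.max()) + 1 if len(frames) else 0
    counts = df.groupby("frame")["point_name"].count()
    if len(counts) != n or not (counts == 12).all():
        raise SchemaError("every frame must list exactly the 12 schema points")

    pts = np.full((n, 12, 3), np.nan)
    cols = df["point_name"].map(name_idx).to_numpy()
    pts[frames, cols, 0] = df["x"].to_numpy()
    pts[frames, cols, 1] = df["y"].to_numpy()
    pts[frames, cols, 2] = df["confidence"].to_numpy()
    seq = KeypointSequence(
        body=pts[:, :8],
        mouth=pts[:, 8:],
        fps=float(header["fps"]),
        frame_size=(int(w), int(h)),
        meta=header.get("meta", ""),
    )
    _normalise_missing(seq)
    return seq


def _normalise_missing(seq: KeypointSequence) -> None:
    """Force the canonical missing encoding (conf 0, NaN coords) in place."""
    for arr in (seq.body, seq.mouth):
        conf = arr[:, :, 2]
        conf[~np.isfinite(conf)] = 0.0
        miss = (conf <= 0) | ~np.isfinite(arr[:, :, 0]) | ~np.isfinite(arr[:, :, 1])
        arr[miss, 0] = np.nan
        arr[miss, 1] = np.nan
        arr[miss, 2] = 0.0


def read_keypoints(path, dialect: str = "json_frames") -> KeypointSequence:
    """Read a keypoint sequence; see the module docstring for the dialects.

    Points outside the frame bounds are kept but reported with a warning;
    missing fps/frame_size metadata raises :class:`SchemaError` (it is never
    guessed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "json_frames":
        seq = _load_json_frames(path)
    elif dialect == "csv_flat":
        seq = _load_csv_flat(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    oob = seq.out_of_bounds_mask()
    if oob.any():
        frames = np.unique(np.nonzero(oob)[0])
        warnings.warn(
            f"{path.name}: {int(oob.sum())} point(s) outside frame bounds "
            f"(frames {frames[:5].tolist()}{'...' if len(frames) > 5 else ''})",
            stacklevel=2,
        )
    return seq


# ---------------------------------------------------------------------------
# annotation logs
# ---------------------------------------------------------------------------

def write_annotations(log: AnnotationLog, path) -> None:
    """Write an event log as a ``time_s,event`` CSV."""
    with Path(path).open("w") as fh:
        fh.write("time_s,event\n")
        for t, k in zip(log.times, log.kinds):
            fh.write(f"{_TIME_FMT % t},{k}\n")


def read_annotations(path, source: str = "manual") -> AnnotationLog:
    """Read a ``time_s,event`` CSV into an :class:`AnnotationLog`.

    Rows out of time order are sorted with a warning; unknown event names
    and negative times are rejected.
    """
    df = pd.read_csv(path)
    if not {"time_s", "event"}.issubset(df.columns):
        raise SchemaError("annotation CSV requires columns time_s, event")
    times = df["time_s"].to_numpy(dtype=float)
    kinds = [str(k) for k in df["event"]]
    if np.any(np.diff(times) < 0):
        warnings.warn(f"{Path(path).name}: events out of order; sorting", stacklevel=2)
    return AnnotationLog.from_events(zip(times, kinds), source=source, sort=True)


def write_behavior_log(summary, events: AnnotationLog, path) -> None:
    """Write the behavioural output for one meal: event CSV + summary sidecar.

    ``path`` is the event CSV; a JSON sidecar ``<path>.summary.json`` holds
    duration, bite counts, per-segment counts and (optionally) quadratic-fit
    coefficients.  Re-reading the CSV reproduces ``events``; writing again
    produces identical bytes.
    """
    path = Path(path)
    if summary.total_bites != len(events.bite_times()):
        raise ValueError("summary total_bites inconsistent with event log")
    write_annotations(events, path)
    doc = summary.to_dict()
    sidecar = path.with_suffix(path.suffix + ".summary.json")
    sidecar.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
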