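"""Per-meal behavioural outcomes.

From a timestamped event log this module derives the measures used for
meal-microstructure analysis: meal duration, total bites, bite counts per
10% segment of the meal, and a quadratic model of how the bite rate evolves
as the meal progresses (``y = y0 + a*x + b*x**2`` over segment indices
``x = 1..10``).  Higher rates at both meal ends with a slower middle show up
as ``a < 0, b > 0``.

Meal anchoring differs by annotation source and is deliberate: manual logs
anchor the meal start at the first spoonful (falling back to an explicit
``meal_start`` event, then to the first bite) because the spoonful marks
food leaving the plate; detected logs contain only bites, so the meal spans
first to last detected bite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .keypoint_io import AnnotationLog

__all__ = [
    "MealSummary",
    "QuadraticFit",
    "meal_summary",
    "segment_bite_rates",
    "average_segment_profile",
    "fit_quadratic",
]


@dataclass
class QuadraticFit:
    """Coefficients of ``y = y0 + a*x + b*x**2`` with the fit's RSS."""

    y0: float
    a: float
    b: float
    rss: float = 0.0

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.y0 + self.a * x + self.b * x * x

    def coefficients(self) -> tuple[float, float, float]:
        return (self.y0, self.a, self.b)


@dataclass
class MealSummary:
    """Duration, bite totals and per-segment bite counts for one meal."""

    duration_min: float | None
    total_bites: int
    segment_counts: tuple[int, ...]
    start_s: float | None
    stop_s: float | None
    source: str = "manual"
    fit: QuadraticFit | None = None

    def __post_init__(self) -> None:
        if self.total_bites and sum(self.segment_counts) != self.total_bites:
            raise ValueError("segment counts must sum to total bites")
        if self.duration_min is not None and self.duration_min < 0:
            raise ValueError("negative meal duration")

    @classmethod
    def empty(cls, source: str = "manual") -> "MealSummary":
        """Degenerate summary for a log with no bites: duration undefined."""
        return cls(
            duration_min=None,
            total_bites=0,
            segment_counts=(0,) * 10,
            start_s=None,
            stop_s=None,
            source=source,
        )

    @property
    def duration_defined(self) -> bool:
        return self.duration_min is not None

    def to_dict(self) -> dict:
        doc = {
            "duration_min": self.duration_min,
            "duration_defined": self.duration_defined,
            "total_bites": self.total_bites,
            "segment_counts": list(self.segment_counts),
            "start_s": self.start_s,
            "stop_s": self.stop_s,
            "source": self.source,
        }
        if self.fit is not None:
            doc["fit"] = {
                "y0": self.fit.y0,
                "a": self.fit.a,
                "b": self.fit.b,
                "rss": self.fit.rss,
            }
        return doc


class UndefinedDurationError(ValueError):
    """Raised when a meal summary is requested for a log with no bites."""


def meal_summary(log: AnnotationLog, n_segments: int = 10) -> MealSummary:
    """Summarise one meal log into duration, bite counts and segment counts.

    Manual logs: start = first spoonful, falling back to the ``meal_start``
    event, then to the first bite; stop = last bite.  Detected logs: start
    and stop are the first and last detected bite.
    """
    bites = log.bite_times()
    if len(bites) == 0:
        raise UndefinedDurationError("log contains no bites; meal duration undefined")
    if log.source == "manual":
        spoonfuls = log.of_kind("spoonful")
        starts = log.of_kind("meal_start")
        if len(spoonfuls):
            start = float(spoonfuls[0])
        elif len(starts):
            start = float(starts[0])
        else:
            start = float(bites[0])
    else:
        start = float(bites[0])
    stop = float(bites[-1])
    counts = segment_bite_rates(bites, start, stop, n_segments=n_segments)
    return MealSummary(
        duration_min=(stop - start) / 60.0,
        total_bites=len(bites),
        segment_counts=tuple(int(c) for c in counts),
        start_s=start,
        stop_s=stop,
        source=log.source,
    )


def segment_bite_rates(
    bite_times: Sequence[float],
    start_s: float,
    stop_s: float,
    n_segments: int = 10,
) -> np.ndarray:
    """Count bites per equal segment of the meal.

    Segment ``i`` (1-based) covers ``[start + (i-1)*D/n, start + i*D/n)``
    with the final segment closed on the right, so a bite exactly at
    ``stop_s`` lands in the last segment and the counts always sum to the
    number of bites.
    """
    bites = np.asarray(bite_times, dtype=float)
    if not stop_s > start_s:
        if len(bites) and not np.all(bites == start_s):
            raise ValueError("stop_s must exceed start_s")
        counts = np.zeros(n_segments, dtype=int)
        counts[-1] = len(bites)  # zero-length meal: everything in the last bin
        return counts
    if len(bites) and (bites.min() < start_s or bites.max() > stop_s):
        raise ValueError("bite outside the meal bounds")
    duration = stop_s - start_s
    frac = (bites - start_s) / duration
    idx = np.minimum((frac * n_segments).astype(int), n_segments - 1)
    return np.bincount(idx, minlength=n_segments).astype(int)


def average_segment_profile(profiles: Sequence[Sequence[float]]) -> np.ndarray:
    """Element-wise mean of per-meal segment counts (all the same length)."""
    arrs = [np.asarray(p, dtype=float) for p in profiles]
    if not arrs:
        raise ValueError("no profiles to average")
    n = arrs[0].shape
    if any(a.shape != n for a in arrs):
        raise ValueError("profiles have differing lengths")
    return np.mean(arrs, axis=0)


def fit_quadratic(profile: Sequence[float], x: Sequence[float] | None = None) -> QuadraticFit:
    """Ordinary least squares of ``y = y0 + a*x + b*x**2``.

    ``x`` defaults to the 1-based segment index ``1..len(profile)``.  Exact
    (RSS 0) when the input lies on a quadratic.
    """
    y = np.asarray(profile, dtype=float)
    if x is None:
        xv = np.arange(1, len(y) + 1, dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
    if len(np.unique(xv)) < 3:
        raise ValueError("quadratic fit needs at least 3 distinct x values")
    design = np.column_stack([np.ones_like(xv), xv, xv * xv])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return QuadraticFit(y0=float(coef[0]), a=float(coef[1]), b=float(coef[2]),
                        rss=float(resid @ resid))
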