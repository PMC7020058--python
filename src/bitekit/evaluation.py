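"""Agreement statistics between two annotation sources.

Three levels of comparison:

* **Clip level** — a confusion matrix of bite / non-bite window labels
  (rows manual, columns automatic) summarized by Cohen's kappa, recall,
  specificity and two F1 variants.  ``f1_bite`` is the standard harmonic
  mean of precision and recall on the bite class; ``f1_rs`` is the
  harmonic mean of recall and specificity.  Both are always reported and
  labelled because the two are easily conflated in the literature;
  ``f1_bite`` is the headline value here.
* **Event level** — one-to-one matching of detected to reference bite
  timestamps within a tolerance, giving precision/recall/F1 on events.
* **Measure level** — Pearson correlation of per-meal measures (total
  bites, duration) between the two sources, with qualitative bands at
  R^2 >= 0.50 / 0.75 / 0.90 ("medium" / "high" / "very high").

Kappa interpretation convention: values above 0.80 are read as near
perfect agreement, 0.60-0.80 as satisfactory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .keypoint_io import AnnotationLog

__all__ = [
    "ConfusionMatrix",
    "AgreementMetrics",
    "MatchResult",
    "CorrelationResult",
    "confusion_metrics",
    "match_events",
    "correlate_measures",
    "kappa_band",
]


@dataclass
class ConfusionMatrix:
    """Bite = positive class; rows are manual labels, columns automatic."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def transposed(self) -> "ConfusionMatrix":
        return ConfusionMatrix(tp=self.tp, fn=self.fp, fp=self.fn, tn=self.tn)


@dataclass
class AgreementMetrics:
    kappa: float
    recall: float
    specificity: float
    precision: float
    f1_bite: float
    f1_rs: float

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "recall": self.recall,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1_bite": self.f1_bite,
            "f1_rs": self.f1_rs,
        }


def _harmonic(a: float, b: float) -> float:
    return 0.0 if a + b == 0 else 2.0 * a * b / (a + b)


def kappa_band(kappa: float) -> str:
    if kappa > 0.80:
        return "near perfect"
    if kappa >= 0.60:
        return "satisfactory"
    return "poor"


def confusion_metrics(m: ConfusionMatrix) -> AgreementMetrics:
    """Chance-corrected and rate metrics of a bite/non-bite confusion matrix.

    kappa = (po - pe) / (1 - pe) with po the observed agreement fraction
    and pe the agreement expected from the marginals.  Degenerate marginals
    (pe = 1) make kappa undefined and raise ``ZeroDivisionError``.
    """
    n = m.total
    po = (m.tp + m.tn) / n
    pe = ((m.tp + m.fn) * (m.tp + m.fp) + (m.fp + m.tn) * (m.fn + m.tn)) / (n * n)
    if pe == 1.0:
        raise ZeroDivisionError("kappa undefined: degenerate marginals (pe = 1)")
    kappa = (po - pe) / (1.0 - pe)
    recall = m.tp / (m.tp + m.fn) if m.tp + m.fn else 0.0
    specificity = m.tn / (m.tn + m.fp) if m.tn + m.fp else 0.0
    precision = m.tp / (m.tp + m.fp) if m.tp + m.fp else 0.0
    return AgreementMetrics(
        kappa=kappa,
        recall=recall,
        specificity=specificity,
        precision=precision,
        f1_bite=_harmonic(precision, recall),
        f1_rs=_harmonic(recall, specificity),
    )


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    precision: float | None  # None when undefined (no detections)
    recall: float
    f1: float

    @property
    def precision_defined(self) -> bool:
        return self.precision is not None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "precision_defined": self.precision_defined,
            "recall": self.recall,
            "f1": self.f1,
        }


def _bite_times(log) -> np.ndarray:
    if isinstance(log, AnnotationLog):
        if any(k != "bite" for k in log.kinds):
            raise ValueError("event matching expects bite-only logs")
        return log.times
    return np.sort(np.asarray(log, dtype=float))


def match_events(
    detected, reference, tolerance_s: float = 1.0
) -> MatchResult:
    """Maximum one-to-one matching of detected to reference bites.

    Two bites may be paired when they are at most ``tolerance_s`` apart.
    On sorted timestamps a two-pointer greedy scan attains the maximum
    cardinality (interval matching on a line).  With no detections and no
    references all rates are 1; with references but no detections recall
    is 0 and precision is flagged undefined (``None``).
    """
    det = _bite_times(detected)
    ref = _bite_times(reference)
    i = j = tp = 0
    while i < len(det) and j < len(ref):
        dt = det[i] - ref[j]
        if abs(dt) <= tolerance_s:
            tp += 1
            i += 1
            j += 1
        elif dt < 0:
            i += 1
        else:
            j += 1
    fp = len(det) - tp
    fn = len(ref) - tp
    if len(det) == 0 and len(ref) == 0:
        return MatchResult(tp=0, fp=0, fn=0, precision=1.0, recall=1.0, f1=1.0)
    precision = tp / len(det) if len(det) else None
    recall = tp / len(ref) if len(ref) else 1.0
    if precision is None or precision + recall == 0:
        f1 = 0.0
    else:
        f1 = _harmonic(precision, recall)
    return MatchResult(tp=int(tp), fp=int(fp), fn=int(fn),
                       precision=precision, recall=recall, f1=f1)


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    band: str
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "r_squared": self.r_squared, "band": self.band, "n": self.n}


def correlate_measures(pairs: Sequence[tuple[float, float]]) -> CorrelationResult:
    """Pearson correlation of per-meal (manual, detected) measure pairs.

    Requires at least 3 pairs with non-zero variance on both sides.  The
    qualitative band follows the R^2 >= 0.50 / 0.75 / 0.90 convention.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    if np.isclose(arr[:, 0].std(), 0) or np.isclose(arr[:, 1].std(), 0):
        raise ValueError("correlation undefined: zero variance in one coordinate")
    r = float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)
    r2 = r * r
    if r2 >= 0.90:
        band = "very high"
    elif r2 >= 0.75:
        band = "high"
    elif r2 >= 0.50:
        band = "medium"
    else:
        band = "low"
    return CorrelationResult(r=r, r_squared=r2, band=band, n=arr.shape[0])
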