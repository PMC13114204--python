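"""Segment-based, event-based and AUROC evaluation, plus table aggregation.

Event scoring uses the any-overlap rule on half-open intervals: a marked
seizure counts as detected iff at least one predicted event overlaps it;
a predicted event is a false detection iff it overlaps no marked seizure;
multiple predictions on one seizure count once and are not false.  The
false detection rate (FDR) is false events per hour of test recording.

The AUROC variant applies one fixed post-processing to every patient: a
24 s moving-average (six 4 s segments — three past, the current one and
two future) on the scores, and a 24 s collar dilation of the reference
labels; the area is then the usual midrank statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .io import SeizureInterval
from .postprocess import EventSet, ScoreSequence, collar_extend


@dataclass
class MetricsReport:
    sensitivity_pct: float | None
    specificity_pct: float | None
    accuracy_pct: float
    event_sensitivity_pct: float | None
    detected_events: int
    marked_events: int
    fdr_per_hour: float
    auroc: float | None
    test_hours: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def summary(self) -> str:
        def fmt(v, suffix=""):
            return "n/a" if v is None else f"{v:.2f}{suffix}"

        lines = [
            "Seizure detection report",
            "------------------------",
            f"segment sensitivity : {fmt(self.sensitivity_pct, ' %')}",
            f"segment specificity : {fmt(self.specificity_pct, ' %')}",
            f"segment accuracy    : {fmt(self.accuracy_pct, ' %')}",
            f"event sensitivity   : {fmt(self.event_sensitivity_pct, ' %')}"
            f"  ({self.detected_events}/{self.marked_events} events)",
            f"false detections    : {self.fdr_per_hour:.2f} /h over "
            f"{self.test_hours:.2f} h",
            f"AUROC (fixed 24 s)  : {fmt(self.auroc)}",
        ]
        return "\n".join(lines)


def segment_metrics(predicted: np.ndarray, truth: np.ndarray):
    """(sensitivity %, specificity %, accuracy %) from binary label vectors.

    With no positive (negative) reference segments the sensitivity
    (specificity) is undefined and reported as None.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    sens = 100.0 * tp / (tp + fn) if tp + fn else None
    spec = 100.0 * tn / (tn + fp) if tn + fp else None
    acc = 100.0 * (tp + tn) / truth.size
    return sens, spec, acc


def event_metrics(predicted: EventSet, truth: Sequence[SeizureInterval],
                  test_hours: float):
    """(event sensitivity %, FDR/h, detected count, marked count)."""
    if test_hours <= 0:
        raise ValueError("test_hours must be positive")
    truth = list(truth)
    detected = sum(
        any(t.overlaps(p.onset_s, p.offset_s) for p in predicted) for t in truth
    )
    false_events = sum(
        not any(t.overlaps(p.onset_s, p.offset_s) for t in truth)
        for p in predicted
    )
    sens = 100.0 * detected / len(truth) if truth else None
    return sens, false_events / test_hours, detected, len(truth)


def _fixed_smooth_6tap(x: np.ndarray) -> np.ndarray:
    """24 s mean over six 4 s segments: 3 past, current, 2 future (shrunken
    at the boundaries)."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(len(x))
    lo = np.maximum(t - 3, 0)
    hi = np.minimum(t + 2, len(x) - 1)
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def auroc_fixed_postproc(seq: ScoreSequence, truth: np.ndarray,
                         window_s: float = 24.0) -> float:
    """AUROC under the fixed 24 s smoothing/collar post-processing."""
    truth = np.asarray(truth, dtype=int)
    if truth.shape != seq.scores.shape:
        raise ValueError("labels must align with scores")
    if len(np.unique(truth)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    n_seg = int(round(window_s / seq.segment_duration_s))
    smoothed = _fixed_smooth_6tap(seq.scores) if n_seg == 6 else \
        np.convolve(seq.scores, np.ones(n_seg) / n_seg, mode="same")
    dilated = collar_extend(truth, n_seg)
    return float(roc_auc_score(dilated, smoothed))


def macro_average(values: Sequence[float]):
    """Across-patient mean and standard deviation.

    The SD uses the population (n denominator) convention, which is how
    across-patient spreads are conventionally printed in patient-specific
    seizure-detection summary tables.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to average")
    return float(values.mean()), float(values.std(ddof=0))


def pooled_event_sensitivity(detected: Sequence[int], marked: Sequence[int]) -> float:
    """100 * (sum detected) / (sum marked) across patients."""
    tot = int(np.sum(marked))
    if tot <= 0:
        raise ValueError("no marked events")
    return 100.0 * float(np.sum(detected)) / tot


__all__ = [
    "MetricsReport",
    "segment_metrics",
    "event_metrics",
    "auroc_fixed_postproc",
    "macro_average",
    "pooled_event_sensitivity",
]
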