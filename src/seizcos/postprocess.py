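"""Score post-processing: smoothing, thresholding, collar, calibration.

Per-segment seizure probabilities are turned into stable event decisions by

1. a moving-average filter (MAF) with half-window ``N`` —
   ``y_t = mean(x_{t-N} .. x_{t+N})``, with shrunken windows at the
   sequence boundaries so the output stays length-preserving;
2. a strict threshold ``Thr`` (label 1 iff ``y_t > Thr``);
3. a collar that extends every detected run by ``K`` segments on each side.

The triple ``(N, Thr, K)`` is a patient-specific operating point tuned on a
seizure-free calibration stream: among grid points whose pipeline still
detects every training seizure event, pick the one with the fewest
calibration false alarms (ties: smaller K, smaller N, Thr nearest 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .io import SeizureInterval


@dataclass
class ScoreSequence:
    """Per-segment seizure scores on a uniform time grid."""

    scores: np.ndarray
    segment_duration_s: float = 4.0
    origin_s: float = 0.0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size < 1:
            raise ValueError("scores must be a non-empty vector")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class PostprocParams:
    N: int = 2        # MAF half-window, segments
    Thr: float = 0.5  # decision threshold
    K: int = 1        # collar extension, segments

    def __post_init__(self):
        if self.N < 0 or self.K < 0:
            raise ValueError("N and K must be >= 0")
        if not (0.0 < self.Thr < 1.0):
            raise ValueError("Thr must lie in (0, 1)")


@dataclass
class EventSet:
    """Sorted, non-overlapping predicted seizure intervals."""

    events: list[SeizureInterval] = field(default_factory=list)

    def __post_init__(self):
        evs = sorted(self.events)
        for a, b in zip(evs, evs[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError("events must be non-overlapping")
        self.events = evs

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def maf_smooth(seq: ScoreSequence, N: int) -> ScoreSequence:
    """Centered moving-average with half-window ``N``; boundary points use the
    mean over the in-range part of the window."""
    if N < 0:
        raise ValueError("N must be >= 0")
    x = seq.scores
    if N == 0:
        return ScoreSequence(x.copy(), seq.segment_duration_s, seq.origin_s)
    c = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(len(x))
    lo = np.maximum(t - N, 0)
    hi = np.minimum(t + N, len(x) - 1)
    y = (c[hi + 1] - c[lo]) / (hi - lo + 1)
    return ScoreSequence(np.clip(y, 0.0, 1.0), seq.segment_duration_s, seq.origin_s)


def binarize(seq: ScoreSequence, Thr: float) -> np.ndarray:
    """Strict threshold: label 1 iff score > Thr."""
    if not (0.0 < Thr < 1.0):
        raise ValueError("Thr must lie in (0, 1)")
    return (seq.scores > Thr).astype(int)


def collar_extend(labels: np.ndarray, K: int) -> np.ndarray:
    """Dilate every maximal run of 1s by ``K`` positions on each side."""
    if K < 0:
        raise ValueError("K must be >= 0")
    labels = np.asarray(labels, dtype=int)
    if K == 0 or labels.size == 0:
        return labels.copy()
    out = np.zeros_like(labels)
    idx = np.flatnonzero(labels)
    for i in idx:
        out[max(i - K, 0) : i + K + 1] = 1
    return out


def labels_to_events(labels: np.ndarray, segment_duration_s: float,
                     origin_s: float = 0.0) -> EventSet:
    """Each maximal run of positive segments [i..j] becomes the interval
    ``[origin + i*d, origin + (j+1)*d)``."""
    labels = np.asarray(labels, dtype=int)
    events = []
    d = segment_duration_s
    padded = np.concatenate([[0], labels, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for i, j in zip(starts, ends):
        events.append(SeizureInterval(origin_s + i * d, origin_s + j * d))
    return EventSet(events)


def apply_pipeline(seq: ScoreSequence, params: PostprocParams) -> EventSet:
    """smooth -> threshold -> collar -> events."""
    y = maf_smooth(seq, params.N)
    labels = collar_extend(binarize(y, params.Thr), params.K)
    return labels_to_events(labels, seq.segment_duration_s, seq.origin_s)


def default_grid() -> list[PostprocParams]:
    return [PostprocParams(N, Thr, K)
            for N, Thr, K in product(range(7), np.round(np.arange(0.1, 1.0, 0.1), 10),
                                     range(7))]


class CalibrationWarning(UserWarning):
    pass


def calibrate(
    calibration_scores: ScoreSequence,
    train_scores: ScoreSequence,
    train_events: Sequence[SeizureInterval],
    grid: Sequence[PostprocParams] | None = None,
) -> PostprocParams:
    """Choose the patient-specific operating point ``(N, Thr, K)``.

    ``calibration_scores`` come from a seizure-free stream (every predicted
    event there is a false alarm); ``train_scores`` are the model's scores on
    the training-seizure stream whose ground-truth events are
    ``train_events``.  Feasible grid points must detect (any-overlap) all
    training events; among them, minimize calibration alarms with ties
    broken by smaller K, then smaller N, then Thr nearest 0.5.  If no point
    is feasible, warn and return the point maximizing training-event
    detection, then minimizing alarms.
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("calibration grid is empty")
    train_events = list(train_events)

    rows = []
    for p in grid:
        alarms = len(apply_pipeline(calibration_scores, p))
        pred = apply_pipeline(train_scores, p)
        detected = sum(
            any(ev.overlaps(pr.onset_s, pr.offset_s) for pr in pred)
            for ev in train_events
        )
        rows.append((p, alarms, detected))

    feasible = [(p, a) for p, a, d in rows if d == len(train_events)]
    if feasible:
        return min(feasible, key=lambda t: (t[1], t[0].K, t[0].N,
                                            abs(t[0].Thr - 0.5)))[0]
    warnings.warn(
        "no grid point detects all training seizure events; "
        "returning the best-detection point",
        CalibrationWarning,
    )
    return min(rows, key=lambda t: (-t[2], t[1], t[0].K, t[0].N,
                                    abs(t[0].Thr - 0.5)))[0]


__all__ = [
    "ScoreSequence", "PostprocParams", "EventSet", "CalibrationWarning",
    "maf_smooth", "binarize", "collar_extend", "labels_to_events",
    "apply_pipeline", "default_grid", "calibrate",
]
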