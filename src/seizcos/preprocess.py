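"""DWT sub-band filtering, segmentation, and patient-specific set construction.

The preprocessing chain mirrors a patient-specific long-term-monitoring
protocol:

1. Each channel is band-filtered by a 5-level Daubechies-4 discrete wavelet
   decomposition, keeping only the d3-d5 detail bands (4-32 Hz at 256 Hz)
   and reconstructing — applied to the continuous recording before any
   windowing so window edges see no transform transients.
2. The continuous record is cut into fixed 4 s windows (T=1024 samples at
   256 Hz) across all channels synchronously; a window is labeled ictal iff
   it overlaps any annotated seizure interval (any-overlap rule).
3. Training material is oversampled: the selected training seizure events
   are concatenated into one ictal stream and windowed with step
   ``floor(T / n_over)`` (~80 % overlap at n_over=5); interictal training
   comes from ``2*n_over`` seizure-free chunks of length ``L_sz/2`` each
   (L_sz = total training-seizure duration), windowed without overlap, so
   the interictal training duration is about ``n_over * L_sz``.
4. A contiguous 20 min seizure-free span is reserved for post-processing
   calibration; it is disjoint from training chunks and from the test
   stream.  Everything else, in chronological order, is the test stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .io import Recording, SeizureInterval, merge_intervals


class DataError(ValueError):
    """Not enough material to honor the requested split."""


# ---------------------------------------------------------------------------
# DWT sub-band filter

def dwt_subband_filter(
    signal: np.ndarray,
    wavelet: str = "db4",
    levels: int = 5,
    keep_bands: Sequence[str] = ("d3", "d4", "d5"),
) -> np.ndarray:
    """Reconstruct a signal from a subset of its DWT sub-bands.

    A ``levels``-deep decomposition yields detail bands ``d1..d<levels>``
    (d1 the highest octave) and the approximation ``a<levels>``.  All
    coefficient arrays outside ``keep_bands`` are zeroed before the inverse
    transform.  Output length equals input length.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal; filter recordings per channel")
    if x.size < 2 ** levels:
        raise ValueError(f"signal too short for a {levels}-level DWT")
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric")
    names = [f"a{levels}"] + [f"d{levels - i}" for i in range(levels)]
    keep = {b.lower() for b in keep_bands}
    unknown = keep - set(names)
    if unknown:
        raise ValueError(f"unknown sub-bands {sorted(unknown)}; have {names}")
    kept = [c if name in keep else np.zeros_like(c)
            for name, c in zip(names, coeffs)]
    out = pywt.waverec(kept, wavelet, mode="symmetric")
    return out[: x.size]


def filter_recording(rec: Recording, wavelet: str = "db4", levels: int = 5,
                     keep_bands: Sequence[str] = ("d3", "d4", "d5")) -> Recording:
    """Apply :func:`dwt_subband_filter` independently to every channel."""
    data = np.vstack([
        dwt_subband_filter(row, wavelet, levels, keep_bands) for row in rec.data
    ])
    return Recording(list(rec.channel_labels), rec.fs, data, list(rec.annotations))


# ---------------------------------------------------------------------------
# segmentation

@dataclass
class SegmentSet:
    """Windowed multichannel samples with binary labels and source times."""

    X: np.ndarray          # (n, C, T)
    y: np.ndarray          # (n,) in {0, 1}
    start_s: np.ndarray    # (n,) seconds in the source timeline
    fs: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=int)
        self.start_s = np.asarray(self.start_s, dtype=float)
        if self.X.ndim != 3 or len(self.y) != len(self.X) or len(self.start_s) != len(self.X):
            raise ValueError("inconsistent segment set")
        if self.y.size and not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.start_s.size and self.start_s.min() < 0:
            raise ValueError("negative start time")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def T(self) -> int:
        return self.X.shape[2]

    @property
    def segment_duration_s(self) -> float:
        return self.T / self.fs

    @staticmethod
    def concatenate(parts: Sequence["SegmentSet"]) -> "SegmentSet":
        return SegmentSet(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.start_s for p in parts]),
            parts[0].fs,
        )


def _window_starts(n_samples: int, T: int, step: int) -> np.ndarray:
    if n_samples < T:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - T + 1, step, dtype=int)


def label_segments(rec: Recording, T: int, step: int) -> SegmentSet:
    """Cut ``rec`` into full-length windows of ``T`` samples every ``step``
    samples; label 1 iff the window's time span overlaps any annotation."""
    if T > rec.n_samples:
        return SegmentSet(np.empty((0, rec.n_channels, T)), [], [], rec.fs)
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = _window_starts(rec.n_samples, T, step)
    X = np.stack([rec.data[:, s : s + T] for s in starts]) if starts.size else \
        np.empty((0, rec.n_channels, T))
    t0 = starts / rec.fs
    t1 = (starts + T) / rec.fs
    y = np.zeros(starts.size, dtype=int)
    for iv in rec.annotations:
        y |= (t0 < iv.offset_s) & (iv.onset_s < t1)
    return SegmentSet(X, y, t0, rec.fs)


# ---------------------------------------------------------------------------
# train / calibration / test split

@dataclass
class SplitPlan:
    """Which seizure events train the model and how material is apportioned."""

    train_event_indices: tuple[int, ...] = (0,)
    n_over: int = 5
    T: int = 1024
    calibration_duration_s: float = 1200.0

    def __post_init__(self) -> None:
        if self.n_over < 1:
            raise ValueError("oversampling rate must be >= 1")
        if self.T < 1:
            raise ValueError("window length must be positive")

    @property
    def step(self) -> int:
        """Ictal sliding-window step: floor(T / n_over) (204 at defaults)."""
        return self.T // self.n_over


def _complement_spans(total: int, used: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Contiguous sample spans of [0, total) not covered by ``used``."""
    merged: list[tuple[int, int]] = []
    for a, b in sorted(used):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    out, cur = [], 0
    for a, b in merged:
        if a > cur:
            out.append((cur, a))
        cur = max(cur, b)
    if cur < total:
        out.append((cur, total))
    return out


def _sample_span(iv: SeizureInterval, fs: float) -> tuple[int, int]:
    return int(math.floor(iv.onset_s * fs)), int(math.floor(iv.offset_s * fs))


@dataclass
class Split:
    train: SegmentSet
    calibration: Recording
    test: Recording
    train_events_stream: Recording  # concatenated training seizures, annotated
    train_event_intervals: tuple[SeizureInterval, ...]  # stream coords, unmerged
    calibration_span_s: tuple[float, float]
    chunk_spans_s: tuple[tuple[float, float], ...]


def build_training_set(rec: Recording, plan: SplitPlan) -> Split:
    """Construct the patient-specific training set, calibration stream and
    test stream from one annotated recording.

    Returns a :class:`Split`; ``split.train`` holds the oversampled ictal
    windows (label 1) plus non-overlapping interictal windows (label 0),
    ``split.calibration`` is a contiguous seizure-free recording, and
    ``split.test`` is the remaining recording in chronological order with
    its annotations (training-event spans, interictal training chunks and
    the calibration span are excised).
    """
    fs = rec.fs
    T = plan.T
    ann = rec.annotations
    if not ann:
        raise DataError("recording has no annotated seizures")
    bad = [i for i in plan.train_event_indices if not (0 <= i < len(ann))]
    if bad or not plan.train_event_indices:
        raise DataError(f"invalid training event indices {bad}")

    train_events = [ann[i] for i in sorted(set(plan.train_event_indices))]
    train_spans = [_sample_span(iv, fs) for iv in train_events]
    L_sz = sum(b - a for a, b in train_spans)
    if L_sz < T:
        raise DataError("training seizures shorter than one window")

    # (a) ictal stream: concatenated training events, overlapped windows
    ictal = np.concatenate([rec.data[:, a:b] for a, b in train_spans], axis=1)
    starts = _window_starts(ictal.shape[1], T, plan.step)
    train_ictal = SegmentSet(
        np.stack([ictal[:, s : s + T] for s in starts]),
        np.ones(starts.size, dtype=int),
        starts / fs,
        fs,
    )
    # the same stream as an annotated Recording (for calibration of the
    # event pipeline): each training event mapped into the concatenated axis
    stream_ann, off = [], 0
    for a, b in train_spans:
        stream_ann.append(SeizureInterval(off / fs, (off + (b - a)) / fs))
        off += b - a
    train_stream = Recording(list(rec.channel_labels), fs, ictal, stream_ann)

    # (c) calibration: earliest contiguous seizure-free span that fits
    all_seizure_spans = [_sample_span(iv, fs) for iv in ann]
    free = _complement_spans(rec.n_samples, all_seizure_spans)
    calib_len = int(round(plan.calibration_duration_s * fs))
    calib_span = None
    for a, b in free:
        if b - a >= calib_len:
            calib_span = (a, a + calib_len)
            break
    if calib_span is None:
        raise DataError("no seizure-free span long enough for calibration")

    # (b) interictal chunks: 2*n_over chunks of L_sz/2 samples, uniformly
    # spaced over seizure-free samples not reserved for calibration
    n_chunks = 2 * plan.n_over
    chunk_len = L_sz // 2
    avail = _complement_spans(rec.n_samples, all_seizure_spans + [calib_span])
    total_free = sum(b - a for a, b in avail)
    if total_free < n_chunks * chunk_len:
        raise DataError("insufficient seizure-free material for interictal chunks")
    chunk_spans: list[tuple[int, int]] = []
    cursor = 0  # virtual offset into the concatenated free space
    for s in range(n_chunks):
        want = max(int(round(s * total_free / n_chunks)), cursor)
        placed = None
        while placed is None:
            # map virtual offset -> actual span, shifting right until it fits
            v = 0
            for a, b in avail:
                if want < v + (b - a):
                    start = a + (want - v)
                    if start + chunk_len <= b:
                        placed = (start, start + chunk_len)
                    else:
                        want = v + (b - a)  # jump to next free span
                    break
                v += b - a
            else:
                raise DataError("insufficient seizure-free material for chunks")
        chunk_spans.append(placed)
        cursor = want + chunk_len

    inter = np.concatenate([rec.data[:, a:b] for a, b in chunk_spans], axis=1)
    istarts = _window_starts(inter.shape[1], T, T)
    train_inter = SegmentSet(
        np.stack([inter[:, s : s + T] for s in istarts]),
        np.zeros(istarts.size, dtype=int),
        istarts / fs,
        fs,
    )

    # (d) test: everything not consumed above, in chronological order
    consumed = train_spans + chunk_spans + [calib_span]
    test_spans = _complement_spans(rec.n_samples, consumed)
    parts, test_ann, off = [], [], 0
    for a, b in test_spans:
        parts.append(rec.data[:, a:b])
        for iv in ann:
            sa, sb = _sample_span(iv, fs)
            lo, hi = max(sa, a), min(sb, b)
            if hi > lo:
                test_ann.append(SeizureInterval((off + lo - a) / fs,
                                                (off + hi - a) / fs))
        off += b - a
    test = Recording(list(rec.channel_labels), fs,
                     np.concatenate(parts, axis=1), merge_intervals(test_ann))

    calibration = Recording(list(rec.channel_labels), fs,
                            rec.data[:, calib_span[0] : calib_span[1]].copy())
    return Split(
        train=SegmentSet.concatenate([train_ictal, train_inter]),
        calibration=calibration,
        test=test,
        train_events_stream=train_stream,
        train_event_intervals=tuple(stream_ann),
        calibration_span_s=(calib_span[0] / fs, calib_span[1] / fs),
        chunk_spans_s=tuple((a / fs, b / fs) for a, b in chunk_spans),
    )


__all__ = [
    "DataError",
    "SegmentSet",
    "SplitPlan",
    "Split",
    "dwt_subband_filter",
    "filter_recording",
    "label_segments",
    "build_training_set",
]
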