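"""Recording container, EDF and annotation I/O, montage construction.

A :class:`Recording` is the canonical in-memory object of the package: a
``(n_channels, n_samples)`` float matrix in microvolts with a sampling rate
and an ordered list of annotated seizure intervals.  Intervals follow the
half-open convention ``[onset_s, offset_s)`` with the sample at time ``t``
being index ``floor(t * fs)``.

EDF reading is delegated to :mod:`mne`.  EDF writing is a minimal 16-bit
EDF writer sufficient for fixtures (one-second data records, integer
sampling rates); it is not a general-purpose exporter.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed file or incompatible channel layout."""


class MontageError(KeyError):
    """A derivation references an electrode absent from the recording."""


def _norm_label(label: str) -> str:
    return label.strip().lower()


@dataclass(frozen=True, order=True)
class SeizureInterval:
    """Half-open annotated seizure interval ``[onset_s, offset_s)`` in seconds."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_s < self.offset_s):
            raise ValueError(
                f"invalid interval ({self.onset_s}, {self.offset_s}): "
                "need 0 <= onset < offset"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlaps(self, onset_s: float, offset_s: float) -> bool:
        """Any-overlap test against another half-open interval."""
        return self.onset_s < offset_s and onset_s < self.offset_s


def merge_intervals(intervals: Sequence[SeizureInterval]) -> list[SeizureInterval]:
    """Sort by onset and merge overlapping/touching intervals."""
    out: list[SeizureInterval] = []
    for iv in sorted(intervals):
        if out and iv.onset_s <= out[-1].offset_s:
            if iv.offset_s > out[-1].offset_s:
                out[-1] = SeizureInterval(out[-1].onset_s, iv.offset_s)
        else:
            out.append(SeizureInterval(iv.onset_s, iv.offset_s))
    return out


@dataclass
class Recording:
    """Multichannel EEG recording in microvolts with seizure annotations."""

    channel_labels: list[str]
    fs: float
    data: np.ndarray  # (C, S) microvolts
    annotations: list[SeizureInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (channels, samples) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        self.annotations = merge_intervals(self.annotations)
        for iv in self.annotations:
            if iv.offset_s > self.duration_s + 1e-9:
                raise ValueError(f"annotation {iv} exceeds recording duration")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        wanted = _norm_label(label)
        for i, lab in enumerate(self.channel_labels):
            if _norm_label(lab) == wanted:
                return i
        raise MontageError(f"channel {label!r} not present in recording")


@dataclass(frozen=True)
class Montage:
    """List of derivations ``(name, positive, negative)``.

    ``negative=None`` denotes a referential (pass-through) channel; otherwise
    the derived signal is ``positive - negative`` (a bipolar channel).
    """

    derivations: tuple[tuple[str, str, str | None], ...]

    @classmethod
    def bipolar(cls, pairs: Sequence[str]) -> "Montage":
        """Build from names like ``'FP1-F7'`` (electrode minus electrode)."""
        deriv = []
        for name in pairs:
            pos, neg = name.split("-", 1)
            deriv.append((name, pos, neg))
        return cls(tuple(deriv))

    @classmethod
    def referential(cls, labels: Sequence[str]) -> "Montage":
        return cls(tuple((lab, lab, None) for lab in labels))


#: The 18 bipolar channels shared by CHB-MIT-style longitudinal montages.
CHBMIT_BIPOLAR_18 = Montage.bipolar(
    [
        "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
        "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
        "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
        "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
        "FZ-CZ", "CZ-PZ",
    ]
)


def apply_montage(rec: Recording, montage: Montage) -> Recording:
    """Re-reference a recording: each derivation is ``pos - neg`` (or a copy)."""
    rows = []
    labels = []
    for name, pos, neg in montage.derivations:
        sig = rec.data[rec.channel_index(pos)]
        if neg is not None:
            sig = sig - rec.data[rec.channel_index(neg)]
        rows.append(sig)
        labels.append(name)
    return Recording(labels, rec.fs, np.vstack(rows), list(rec.annotations))


def slice_recording(rec: Recording, start_s: float, end_s: float) -> Recording:
    """Extract samples in ``[start_s, end_s)``; annotations are clipped and
    shifted to the new origin."""
    if not (0.0 <= start_s < end_s <= rec.duration_s + 1e-9):
        raise IndexError(f"slice [{start_s}, {end_s}) out of range")
    i0 = int(math.floor(start_s * rec.fs))
    i1 = int(math.floor(end_s * rec.fs))
    ann = []
    for iv in rec.annotations:
        lo = max(iv.onset_s, start_s) - start_s
        hi = min(iv.offset_s, end_s) - start_s
        if hi > lo:
            ann.append(SeizureInterval(max(lo, 0.0), hi))
    return Recording(list(rec.channel_labels), rec.fs, rec.data[:, i0:i1].copy(), ann)


def concatenate_recordings(parts: Sequence[Recording]) -> Recording:
    """Concatenate recordings end to end on a common channel layout,
    re-referencing annotations into the joined timeline."""
    if not parts:
        raise ValueError("nothing to concatenate")
    fs = parts[0].fs
    labels = parts[0].channel_labels
    ann: list[SeizureInterval] = []
    offset = 0.0
    for p in parts:
        if p.fs != fs or len(p.channel_labels) != len(labels):
            raise FormatError("incompatible recordings")
        ann.extend(SeizureInterval(iv.onset_s + offset, iv.offset_s + offset)
                   for iv in p.annotations)
        offset += p.duration_s
    data = np.concatenate([p.data for p in parts], axis=1)
    return Recording(list(labels), fs, data, ann)


# ---------------------------------------------------------------------------
# annotations: sidecar CSV / JSON

def read_annotations(path: str | Path) -> list[SeizureInterval]:
    """Read seizure intervals from a sidecar CSV (``onset_s,offset_s``) or a
    JSON list of ``[onset, offset]`` pairs; returns sorted, merged intervals."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        pairs = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        if len(df) == 0:
            return []
        missing = {"onset_s", "offset_s"} - set(df.columns)
        if missing:
            raise FormatError(f"annotation CSV lacks columns {sorted(missing)}")
        pairs = df[["onset_s", "offset_s"]].to_numpy().tolist()
    intervals = [SeizureInterval(float(a), float(b)) for a, b in pairs]
    return merge_intervals(intervals)


def write_annotations(intervals: Sequence[SeizureInterval], path: str | Path) -> None:
    path = Path(path)
    intervals = merge_intervals(intervals)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([[iv.onset_s, iv.offset_s] for iv in intervals]))
    else:
        pd.DataFrame(
            {"onset_s": [iv.onset_s for iv in intervals],
             "offset_s": [iv.offset_s for iv in intervals]}
        ).to_csv(path, index=False)


def read_chbmit_summary(path: str | Path, edf_name: str) -> list[SeizureInterval]:
    """Thin converter for CHB-MIT ``*-summary.txt`` files: extract the seizure
    start/end second pairs recorded for one EDF file."""
    text = Path(path).read_text()
    blocks = re.split(r"(?i)file name:\s*", text)[1:]
    for block in blocks:
        name = block.splitlines()[0].strip()
        if name != edf_name:
            continue
        starts = [int(m) for m in re.findall(r"(?i)seizure(?:\s+\d+)?\s+start time:\s*(\d+)", block)]
        ends = [int(m) for m in re.findall(r"(?i)seizure(?:\s+\d+)?\s+end time:\s*(\d+)", block)]
        return merge_intervals([SeizureInterval(float(a), float(b))
                                for a, b in zip(starts, ends)])
    raise FormatError(f"{edf_name} not found in summary file")


# ---------------------------------------------------------------------------
# EDF

def read_edf(path: str | Path, channels: Sequence[str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts).

    Parameters
    ----------
    path : file path
    channels : optional subset of channel labels to keep (case-insensitive);
        all channels must share one sampling rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne raises various types
        raise IOError(f"unreadable EDF {path}: {exc}") from exc
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # mne returns volts
    rec = Recording(labels, float(raw.info["sfreq"]), data)
    if channels is not None:
        idx = [rec.channel_index(c) for c in channels]
        rec = Recording([labels[i] for i in idx], rec.fs, data[idx])
    return rec


def _edf_field(value, width: int) -> bytes:
    raw = str(value).encode("ascii")[:width]
    return raw + b" " * (width - len(raw))


def write_edf(rec: Recording, path: str | Path) -> None:
    """Minimal EDF (16-bit) writer for fixtures.

    Requires an integer sampling rate; the signal is truncated to a whole
    number of one-second data records.  Amplitudes are quantized to the
    16-bit digital range over the recording's physical span.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // fs
    if n_rec < 1:
        raise FormatError("recording shorter than one EDF data record")
    data = rec.data[:, : n_rec * fs]
    C = rec.n_channels
    pmin = float(np.floor(data.min())) - 1.0
    pmax = float(np.ceil(data.max())) + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin) * scale + dmin).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X", 80),
            _edf_field("X", 80),
            _edf_field("01.01.01", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + C), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(1, 8),
            _edf_field(C, 4),
        ]
    )
    cols = [
        [_edf_field(lab, 16) for lab in rec.channel_labels],
        [_edf_field("", 80)] * C,
        [_edf_field("uV", 8)] * C,
        [_edf_field(f"{pmin:.7g}"[:8], 8)] * C,
        [_edf_field(f"{pmax:.7g}"[:8], 8)] * C,
        [_edf_field(dmin, 8)] * C,
        [_edf_field(dmax, 8)] * C,
        [_edf_field("", 80)] * C,
        [_edf_field(fs, 8)] * C,
        [_edf_field("", 32)] * C,
    ]
    header += b"".join(b"".join(col) for col in cols)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


__all__ = [
    "Recording",
    "SeizureInterval",
    "Montage",
    "CHBMIT_BIPOLAR_18",
    "FormatError",
    "MontageError",
    "merge_intervals",
    "apply_montage",
    "slice_recording",
    "concatenate_recordings",
    "read_annotations",
    "write_annotations",
    "read_chbmit_summary",
    "read_edf",
    "write_edf",
]
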