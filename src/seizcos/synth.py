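"""Synthetic multichannel scalp-EEG generator with ground-truth annotations.

The generator produces 1/f-like background activity per channel plus
injected seizure episodes built from stereotyped ictal morphologies
(spike-wave composites, rhythmic bursts, isolated sharp waves).  It exists
so the whole detection pipeline — filtering, segmentation, training,
calibration, post-processing, evaluation, Grad-CAM — can be exercised and
tested end to end with exact ground truth; it makes no claim of
physiological realism.

Design notes
------------
* Background: Gaussian white noise spectrally shaped in the frequency
  domain with a ``1/f^(beta/2)`` amplitude profile, drawn independently per
  channel, plus optional deterministic sinusoidal rhythms.
* Seizures: one shared template per event, added to every channel scaled by
  a per-channel random gain in [0.5, 1.5] — a crude stand-in for the
  inter-channel coherence of ictal activity.  The gain is drawn once per
  channel (not per event), emulating a patient-stable spatial distribution
  of ictal activity across the scalp.
* Reproducibility: one global seed spawns a counter-based substream per
  channel, so changing the channel count does not reshuffle the noise of
  the remaining channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Recording, SeizureInterval


class ConfigError(ValueError):
    """Invalid synthetic-recording configuration."""


TEMPLATE_TYPES = ("spike_wave", "rhythmic_burst", "sharp_wave")


@dataclass(frozen=True)
class SeizureEvent:
    onset_s: float
    duration_s: float
    kind: str = "spike_wave"
    gain: float = 5.0

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SynthConfig:
    """Parameters of a synthetic recording.

    Defaults emulate an 18-channel, 256 Hz scalp recording with a 1/f
    background (beta=1) and ~20 uV RMS broadband noise floor.
    """

    n_channels: int = 18
    fs: float = 256.0
    duration_s: float = 600.0
    beta: float = 1.0
    background_rms: float = 20.0  # microvolts
    rhythms: tuple[tuple[float, float], ...] = ((10.0, 5.0),)  # (Hz, uV)
    events: tuple[SeizureEvent, ...] = ()
    seizure_amplitude: float = 50.0  # microvolts at gain 1
    noise_sd: float = 2.0  # additive white sensor noise, uV
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1 or self.fs <= 0 or self.duration_s <= 0:
            raise ConfigError("channels, fs and duration must be positive")
        evs = sorted(self.events, key=lambda e: e.onset_s)
        for e in evs:
            if e.kind not in TEMPLATE_TYPES:
                raise ConfigError(f"unknown seizure type {e.kind!r}")
            if e.gain < 0:
                raise ConfigError("amplitude gain must be >= 0")
            if e.onset_s < 0 or e.offset_s > self.duration_s:
                raise ConfigError(f"event {e} outside recording span")
        for a, b in zip(evs, evs[1:]):
            if b.onset_s < a.offset_s:
                raise ConfigError(
                    f"overlapping events: ({a.onset_s}, {a.offset_s}) and "
                    f"({b.onset_s}, {b.offset_s})"
                )


def make_template(kind: str, duration_s: float, fs: float) -> np.ndarray:
    """Zero-mean, unit-peak ictal waveform of length ``round(duration_s*fs)``.

    ``spike_wave``
        Repeating ~3 Hz composite: a sharp transient followed by a slower
        half-wave of opposite polarity.  The discharge train waxes and
        wanes (~2.5 s bursts separated by ~1 s lulls), as electrographic
        seizures are discontinuous rather than uniform-intensity.
    ``rhythmic_burst``
        ~6 Hz sinusoid with a ramp-up/ramp-down amplitude envelope.
    ``sharp_wave``
        Sparse isolated asymmetric transients (~1 per second).
    """
    if duration_s <= 0:
        raise ConfigError("template duration must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if kind == "spike_wave":
        f = 3.0  # discharge repetition rate, Hz
        phase = (t * f) % 1.0
        spike = np.exp(-0.5 * ((phase - 0.1) / 0.03) ** 2)  # sharp transient
        slow = -np.sin(np.pi * np.clip((phase - 0.2) / 0.7, 0, 1))  # slow wave
        wave = spike + 0.6 * slow
        # waxing-waning envelope: ~2.5 s discharge bursts, ~1 s lulls
        cycle = (t % 3.5) / 3.5
        burst = 0.5 * (1 - np.cos(2 * np.pi * np.clip(cycle / (2.5 / 3.5), 0, 1)))
        wave = wave * (0.15 + 0.85 * burst)
    elif kind == "rhythmic_burst":
        env = np.minimum(t / max(duration_s * 0.25, 1e-9),
                         (duration_s - t) / max(duration_s * 0.25, 1e-9))
        env = np.clip(env, 0.0, 1.0)
        wave = env * np.sin(2 * np.pi * 6.0 * t)
    elif kind == "sharp_wave":
        wave = np.zeros(n)
        period = 1.0  # one transient per second
        k = 0
        while (c := (k + 0.5) * period) < duration_s:
            # asymmetric transient: fast rise, slower decay
            wave += np.where(
                t < c,
                np.exp(-0.5 * ((t - c) / 0.02) ** 2),
                np.exp(-0.5 * ((t - c) / 0.06) ** 2),
            )
            k += 1
    else:
        raise ConfigError(f"unknown seizure type {kind!r}")
    wave = wave - wave.mean()
    peak = np.abs(wave).max()
    if peak > 0:
        wave = wave / peak
    return wave


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, beta: float,
                  rms: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^beta."""
    white = rng.standard_normal(n)
    if beta == 0:
        shaped = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        amp = np.ones_like(freqs)
        nonzero = freqs > 0
        amp[nonzero] = freqs[nonzero] ** (-beta / 2.0)
        amp[0] = 0.0  # no DC drift
        shaped = np.fft.irfft(spec * amp, n=n)
    cur = shaped.std()
    return shaped * (rms / cur) if cur > 0 else shaped


def generate_recording(cfg: SynthConfig) -> Recording:
    """Generate a reproducible synthetic recording from ``cfg``.

    Same config (including seed) gives bit-identical output.  Annotations
    are exactly the configured events (merged if they touch).
    """
    cfg.validate()
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    root = np.random.SeedSequence(cfg.seed)

    rhythm = np.zeros(n)
    for freq, amp in cfg.rhythms:
        rhythm += amp * np.sin(2 * np.pi * freq * t)

    events = sorted(cfg.events, key=lambda e: e.onset_s)
    templates = []
    for e in events:
        i0 = int(np.floor(e.onset_s * cfg.fs))
        wave = make_template(e.kind, e.duration_s, cfg.fs)
        templates.append((i0, wave))

    data = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        # counter-based substream: channel c always sees the same stream
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(c,)))
        spatial_gain = rng.uniform(0.5, 1.5)  # patient-stable scalp profile
        x = _shaped_noise(rng, n, cfg.fs, cfg.beta, cfg.background_rms)
        x += rhythm
        x += cfg.noise_sd * rng.standard_normal(n)
        for e, (i0, wave) in zip(events, templates):
            x[i0 : i0 + wave.size] += (cfg.seizure_amplitude * e.gain
                                       * spatial_gain * wave)
        data[c] = x

    ann = [SeizureInterval(e.onset_s, e.offset_s) for e in events if e.duration_s > 0]
    labels = [f"CH{i+1:02d}" for i in range(cfg.n_channels)]
    return Recording(labels, cfg.fs, data, ann)


def default_patient_config(
    seed: int = 0,
    *,
    duration_s: float = 7200.0,
    train_seizures: int = 2,
    test_seizures: int = 6,
    gain: float = 6.0,
    kind: str = "spike_wave",
) -> SynthConfig:
    """A standard synthetic "patient": a two-hour 18-channel record with
    ``train_seizures`` early events (reserved for training) and
    ``test_seizures`` later events, leaving a >20 min seizure-free stretch
    for post-processing calibration.

    Seizure durations alternate 30/40 s; events are spaced out over the
    second half of the record.
    """
    events = []
    sz_dur = min(30.0, duration_s / 8.0)
    onset = min(300.0, duration_s * 0.1)
    gap = min(200.0, duration_s * 0.1)
    for i in range(train_seizures):
        events.append(SeizureEvent(onset, sz_dur, kind, gain))
        onset += sz_dur + gap
    # leave a long seizure-free stretch after the training events for
    # post-processing calibration (>=20 min at the default duration)
    onset = max(onset, min(2400.0, duration_s * 0.4))
    span = duration_s - onset - min(300.0, duration_s * 0.05)
    step = span / max(test_seizures, 1)
    for i in range(test_seizures):
        dur = min(40.0 if i % 2 == 0 else 30.0, duration_s / 8.0)
        events.append(SeizureEvent(onset + i * step, dur, kind, gain))
    return SynthConfig(duration_s=duration_s, events=tuple(events), seed=seed)


__all__ = [
    "ConfigError",
    "SeizureEvent",
    "SynthConfig",
    "TEMPLATE_TYPES",
    "make_template",
    "generate_recording",
    "default_patient_config",
]
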