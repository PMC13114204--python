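"""DWT filtering, segmentation/labeling, and split construction."""

import numpy as np
import pytest

from seizcos.io import Recording, SeizureInterval
from seizcos.preprocess import (
    DataError,
    SplitPlan,
    build_training_set,
    dwt_subband_filter,
    filter_recording,
    label_segments,
)


class TestDwtSubbandFilter:
    def test_zero_input_gives_zero_output(self):
        out = dwt_subband_filter(np.zeros(2048))
        assert out.shape == (2048,)
        np.testing.assert_allclose(out, 0.0)

    def test_passband_tone_passes_stopband_tone_blocked(self):
        t = np.arange(8 * 256) / 256.0
        in_band = np.sin(2 * np.pi * 10 * t)   # 10 Hz lies in d4 (8-16 Hz)
        out_band = np.sin(2 * np.pi * 1 * t)   # 1 Hz lies in a5 (0-4 Hz)
        r10 = np.std(dwt_subband_filter(in_band)) / np.std(in_band)
        r1 = np.std(dwt_subband_filter(out_band)) / np.std(out_band)
        assert r10 >= 10 * r1

    def test_keeping_all_bands_reconstructs_input(self, rng):
        x = rng.normal(size=3000)
        out = dwt_subband_filter(x, keep_bands=("d1", "d2", "d3", "d4", "d5", "a5"))
        np.testing.assert_allclose(out, x, rtol=1e-8, atol=1e-8)

    def test_output_length_preserved(self, rng):
        for n in (1000, 1024, 1031):
            assert dwt_subband_filter(rng.normal(size=n)).size == n

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            dwt_subband_filter(np.zeros(16), levels=5)

    def test_filter_recording_is_per_channel(self, small_recording):
        out = filter_recording(small_recording)
        for c in range(small_recording.n_channels):
            np.testing.assert_allclose(
                out.data[c], dwt_subband_filter(small_recording.data[c]))


class TestLabelSegments:
    def test_segment_count_non_overlapping(self):
        rec = Recording(["A"], 256.0, np.zeros((1, 2560)))
        assert len(label_segments(rec, 1024, 1024)) == 2

    def test_any_overlap_labels_both_boundary_segments(self):
        rec = Recording(["A"], 256.0, np.zeros((1, 2048)),
                        [SeizureInterval(3.9, 4.1)])
        segs = label_segments(rec, 1024, 1024)
        assert segs.y.tolist() == [1, 1]

    def test_against_brute_force_interval_intersection(self, rng):
        for _ in range(10):
            n_ann = rng.integers(1, 5)
            onsets = np.sort(rng.uniform(0, 18, n_ann))
            ann = [SeizureInterval(float(o), float(o) + float(rng.uniform(0.1, 1.5)))
                   for o in onsets]
            rec = Recording(["A", "B"], 64.0, rng.normal(size=(2, 20 * 64)),
                            ann)
            T, step = 128, 64
            segs = label_segments(rec, T, step)
            for start, label, X in zip(segs.start_s, segs.y, segs.X):
                t1 = start + T / 64.0
                expect = any(iv.onset_s < t1 and start < iv.offset_s
                             for iv in rec.annotations)
                assert bool(label) == expect
                np.testing.assert_array_equal(
                    X, rec.data[:, int(start * 64): int(start * 64) + T])

    def test_step_T_partitions_usable_signal(self, small_recording):
        T = 96
        segs = label_segments(small_recording, T, T)
        n = small_recording.n_samples // T
        assert len(segs) == n
        assert segs.segment_duration_s * len(segs) == pytest.approx(n * T / 64.0)


def _patient_recording(rng, fs=64.0, duration_s=600.0):
    ann = [SeizureInterval(50.0, 60.0), SeizureInterval(100.0, 110.0),
           SeizureInterval(400.0, 412.0), SeizureInterval(520.0, 530.0)]
    data = rng.normal(0, 10, size=(2, int(duration_s * fs)))
    return Recording(["A", "B"], fs, data, ann)


class TestBuildTrainingSet:
    def test_default_plan_step_is_204(self):
        assert SplitPlan(T=1024, n_over=5).step == 204

    def test_ictal_window_enumeration(self, rng):
        # ictal stream of exactly 2048 samples, T=1024, step 204 -> 6 windows
        fs = 256.0
        ann = [SeizureInterval(10.0, 18.0)]  # 8 s * 256 = 2048 samples
        rec = Recording(["A"], fs, rng.normal(size=(1, int(120 * fs))), ann)
        plan = SplitPlan(train_event_indices=(0,), T=1024,
                         calibration_duration_s=30.0)
        split = build_training_set(rec, plan)
        n_ictal = int(split.train.y.sum())
        assert n_ictal == (2048 - 1024) // 204 + 1 == 6

    def test_split_disjointness_and_balance(self, rng):
        rec = _patient_recording(rng)
        plan = SplitPlan(train_event_indices=(0, 1), T=256,
                         calibration_duration_s=120.0)
        split = build_training_set(rec, plan)

        L_sz = 20.0  # two 10 s training events
        # interictal duration ~ n_over * L_sz (one-sample rounding per chunk)
        inter_s = sum(b - a for a, b in split.chunk_spans_s)
        assert inter_s == pytest.approx(plan.n_over * L_sz, abs=0.5)
        assert len(split.chunk_spans_s) == 2 * plan.n_over

        # calibration span is seizure-free and disjoint from chunks
        ca, cb = split.calibration_span_s
        assert cb - ca == pytest.approx(120.0)
        for iv in rec.annotations:
            assert not (iv.onset_s < cb and ca < iv.offset_s)
        for a, b in split.chunk_spans_s:
            assert not (a < cb and ca < b)
            for iv in rec.annotations:
                assert not (iv.onset_s < b and a < iv.offset_s)

        # test stream keeps the held-out seizures and drops training ones
        assert len(split.test.annotations) == 2
        total_test = split.test.duration_s
        assert total_test == pytest.approx(
            rec.duration_s - L_sz - 120.0 - inter_s, abs=1.0)

        # labels: ictal windows all 1, interictal all 0, both present
        assert set(np.unique(split.train.y)) == {0, 1}

    def test_train_event_intervals_keep_identity(self, rng):
        rec = _patient_recording(rng)
        plan = SplitPlan(train_event_indices=(0, 1), T=256,
                         calibration_duration_s=60.0)
        split = build_training_set(rec, plan)
        assert len(split.train_event_intervals) == 2
        assert split.train_event_intervals[0].duration_s == pytest.approx(10.0)

    def test_insufficient_material_raises(self, rng):
        rec = Recording(["A"], 64.0, rng.normal(size=(1, 64 * 100)),
                        [SeizureInterval(10.0, 50.0)])
        with pytest.raises(DataError):
            build_training_set(rec, SplitPlan(train_event_indices=(0,), T=256,
                                              calibration_duration_s=40.0))

    def test_no_annotations_raises(self, rng):
        rec = Recording(["A"], 64.0, rng.normal(size=(1, 6400)))
        with pytest.raises(DataError):
            build_training_set(rec, SplitPlan())
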