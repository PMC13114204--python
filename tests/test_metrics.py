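"""Segment/event metrics, fixed-postprocessing AUROC, table aggregation."""

import numpy as np
import pytest

from seizcos.io import SeizureInterval
from seizcos.metrics import (
    auroc_fixed_postproc,
    event_metrics,
    macro_average,
    pooled_event_sensitivity,
    segment_metrics,
)
from seizcos.postprocess import EventSet, ScoreSequence

# Printed per-patient segment sensitivities of the two evaluation cohorts
# (24-patient pediatric scalp-EEG cohort; 10-patient adult clinical cohort).
COHORT24_SENSITIVITY = [
    100.00, 100.00, 100.00, 100.00, 100.00, 100.00, 100.00, 94.27, 100.00,
    100.00, 100.00, 98.32, 81.11, 100.00, 98.97, 100.00, 100.00, 87.50,
    100.00, 98.63, 100.00, 100.00, 100.00, 92.65,
]
COHORT24_SPECIFICITY = [
    99.71, 99.72, 99.07, 97.56, 99.95, 96.99, 99.92, 95.14, 100.00, 99.97,
    99.92, 97.31, 98.19, 96.70, 98.86, 91.34, 99.92, 99.70, 99.92, 97.10,
    99.85, 99.99, 99.70, 98.28,
]
COHORT10_SENSITIVITY = [
    81.58, 73.05, 88.58, 95.24, 85.90, 87.38, 89.96, 95.08, 100.00, 84.17,
]


class TestSegmentMetrics:
    def test_perfect_prediction(self):
        sens, spec, acc = segment_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (sens, spec, acc) == (100.0, 100.0, 100.0)

    def test_confusion_arithmetic(self):
        sens, spec, acc = segment_metrics([1, 1, 0, 0], [1, 0, 1, 0])
        assert (sens, spec, acc) == (50.0, 50.0, 50.0)

    def test_undefined_sensitivity_reported_as_none(self):
        sens, spec, acc = segment_metrics([0, 0], [0, 0])
        assert sens is None
        assert spec == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_metrics([1, 0], [1])

    def test_matches_brute_force_confusion_matrix(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 2, 100)
            true = rng.integers(0, 2, 100)
            sens, spec, acc = segment_metrics(pred, true)
            tp = sum(p == 1 and t == 1 for p, t in zip(pred, true))
            tn = sum(p == 0 and t == 0 for p, t in zip(pred, true))
            fp = sum(p == 1 and t == 0 for p, t in zip(pred, true))
            fn = sum(p == 0 and t == 1 for p, t in zip(pred, true))
            assert acc == pytest.approx(100 * (tp + tn) / 100)
            if tp + fn:
                assert sens == pytest.approx(100 * tp / (tp + fn))
            if tn + fp:
                assert spec == pytest.approx(100 * tn / (tn + fp))


def _random_events(rng, n, span=1000.0):
    starts = np.sort(rng.uniform(0, span, n))
    events, cur = [], -1.0
    for s in starts:
        s = max(s, cur + 1e-6)
        e = s + float(rng.uniform(0.5, 20))
        events.append(SeizureInterval(s, e))
        cur = e
    return events


class TestEventMetrics:
    def test_exact_predictions_are_perfect(self):
        truth = [SeizureInterval(10, 20), SeizureInterval(50, 70)]
        sens, fdr, det, marked = event_metrics(EventSet(list(truth)), truth, 2.0)
        assert (sens, fdr, det, marked) == (100.0, 0.0, 2, 2)

    def test_one_prediction_spanning_two_seizures(self):
        truth = [SeizureInterval(10, 20), SeizureInterval(30, 40)]
        pred = EventSet([SeizureInterval(5, 45)])
        sens, fdr, det, marked = event_metrics(pred, truth, 1.0)
        assert (sens, fdr, det) == (100.0, 0.0, 2)

    def test_multiple_hits_count_once_and_are_not_false(self):
        truth = [SeizureInterval(10, 30)]
        pred = EventSet([SeizureInterval(12, 14), SeizureInterval(20, 22)])
        sens, fdr, det, marked = event_metrics(pred, truth, 1.0)
        assert (sens, det, fdr) == (100.0, 1, 0.0)

    def test_matches_pairwise_overlap_oracle(self, rng):
        for _ in range(200):
            truth = _random_events(rng, int(rng.integers(1, 8)))
            pred = EventSet(_random_events(rng, int(rng.integers(0, 10))))
            hours = 2.5
            sens, fdr, det, marked = event_metrics(pred, truth, hours)
            det_o = sum(
                any(p.onset_s < t.offset_s and t.onset_s < p.offset_s
                    for p in pred) for t in truth)
            false_o = sum(
                not any(p.onset_s < t.offset_s and t.onset_s < p.offset_s
                        for t in truth) for p in pred)
            assert det == det_o
            assert marked == len(truth)
            assert sens == pytest.approx(100 * det_o / len(truth))
            assert fdr == pytest.approx(false_o / hours)

    def test_adding_predictions_never_lowers_sensitivity(self, rng):
        truth = _random_events(rng, 5)
        base = _random_events(rng, 3)
        more = EventSet(base + [SeizureInterval(2000.0, 2010.0)])
        s1 = event_metrics(EventSet(base), truth, 1.0)[0]
        s2 = event_metrics(more, truth, 1.0)[0]
        assert s2 >= s1


class TestAurocFixedPostproc:
    @staticmethod
    def _step_case():
        # high scores cover every dilated-positive bin's smoothing window,
        # so the smoothed scores separate the dilated classes perfectly
        x = np.full(100, 0.1)
        x[31:68] = 0.9
        truth = np.zeros(100, int)
        truth[40:60] = 1
        return x, truth

    def test_smoothed_separable_scores_give_one(self):
        x, truth = self._step_case()
        assert auroc_fixed_postproc(ScoreSequence(x), truth) == pytest.approx(1.0)

    def test_reversed_scores_give_zero(self):
        x, truth = self._step_case()
        assert auroc_fixed_postproc(ScoreSequence(1 - x), truth) == \
            pytest.approx(0.0)

    def test_permutation_null_is_half(self, rng):
        # sparse seizure labels placed independently of the scores
        scores = ScoreSequence(rng.random(2000))
        truth = np.zeros(2000, int)
        truth[rng.choice(2000, 40, replace=False)] = 1
        assert auroc_fixed_postproc(scores, truth) == pytest.approx(0.5, abs=0.05)

    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            auroc_fixed_postproc(ScoreSequence(rng.random(10)),
                                 np.zeros(10, int))

    def test_invariant_to_affine_score_rescaling(self, rng):
        # smoothing precedes ranking, so invariance holds for order- and
        # mean-preserving (affine) transforms of the scores
        x = rng.random(300)
        truth = np.zeros(300, int)
        truth[rng.choice(300, 12, replace=False)] = 1
        a = auroc_fixed_postproc(ScoreSequence(x), truth)
        b = auroc_fixed_postproc(ScoreSequence(0.5 * x + 0.2), truth)
        assert a == pytest.approx(b, abs=1e-12)


class TestAggregation:
    def test_cohort24_sensitivity_average(self):
        mean, sd = macro_average(COHORT24_SENSITIVITY)
        assert mean == pytest.approx(97.98, abs=0.005)
        assert sd == pytest.approx(4.60, abs=0.005)

    def test_cohort24_specificity_average(self):
        mean, sd = macro_average(COHORT24_SPECIFICITY)
        assert mean == pytest.approx(98.53, abs=0.005)
        assert sd == pytest.approx(2.01, abs=0.005)

    def test_cohort10_sensitivity_mean(self):
        mean, _ = macro_average(COHORT10_SENSITIVITY)
        assert mean == pytest.approx(88.09, abs=0.005)

    def test_single_value(self):
        assert macro_average([42.0]) == (42.0, 0.0)

    def test_pooled_event_sensitivity_cohort24(self):
        # 142 of 144 held-out seizures detected across the 24 patients
        assert pooled_event_sensitivity([142], [144]) == pytest.approx(98.61, abs=0.005)

    def test_pooled_all_detected(self):
        assert pooled_event_sensitivity([3, 4], [3, 4]) == 100.0

    def test_pooled_matches_ratio_oracle(self, rng):
        det = rng.integers(0, 10, 12)
        marked = det + rng.integers(1, 5, 12)
        got = pooled_event_sensitivity(det, marked)
        assert got == pytest.approx(100 * det.sum() / marked.sum())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            macro_average([])
        with pytest.raises(ValueError):
            pooled_event_sensitivity([], [])
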