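"""Model/Results facade for patient-specific seizure detection.

:class:`SeizureDetectionModel` is built from one annotated
:class:`~seizcos.io.Recording` plus configuration; ``fit()`` runs the whole
patient-specific pipeline — DWT sub-band filtering, split construction,
network training, post-processing calibration, test-stream scoring — and
returns a :class:`SeizureDetectionResults` carrying the trained network,
the chosen operating point, the detected events, the metrics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .gradcam import branch_maps
from .io import Recording
from .metrics import (MetricsReport, auroc_fixed_postproc, event_metrics,
                      segment_metrics)
from .nn.network import MCCHTSCCNet, ModelConfig, build_model, count_parameters
from .postprocess import (EventSet, PostprocParams, ScoreSequence,
                          apply_pipeline, binarize, calibrate, collar_extend,
                          default_grid, maf_smooth)
from .preprocess import (Split, SplitPlan, build_training_set,
                         filter_recording, label_segments)
from .train import TrainConfig, TrainHistory, train


class SeizureDetectionModel:
    """Patient-specific seizure detector built from an annotated recording.

    Parameters
    ----------
    recording : annotated multichannel recording (microvolts)
    plan : train/calibration/test split plan (defaults: first seizure event
        for training, 5x ictal oversampling, 20 min calibration)
    net_config : network architecture; input shape is inferred from the
        recording and plan when omitted
    train_config : optimizer schedule (defaults to the full 500-epoch
        schedule; pass ``epochs=...`` to ``fit`` for desk-scale runs)
    grid : post-processing calibration grid over (N, Thr, K)
    keep_bands : DWT sub-bands retained by the front-end filter

    Examples
    --------
    >>> from seizcos import synth, SeizureDetectionModel
    >>> rec = synth.generate_recording(synth.default_patient_config(seed=1))
    >>> res = SeizureDetectionModel(rec).fit(epochs=15, seed=1)
    >>> print(res.summary())                           # doctest: +SKIP
    """

    def __init__(
        self,
        recording: Recording,
        plan: SplitPlan | None = None,
        net_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        grid: Sequence[PostprocParams] | None = None,
        keep_bands: Sequence[str] = ("d3", "d4", "d5"),
    ):
        self.recording = recording
        self.plan = plan or SplitPlan(
            train_event_indices=(0, 1) if len(recording.annotations) > 4 else (0,))
        self.net_config = net_config
        self.train_config = train_config or TrainConfig()
        self.grid = list(grid) if grid is not None else default_grid()
        self.keep_bands = tuple(keep_bands)

    @classmethod
    def from_files(cls, edf_path, annotation_path, montage=None, **kwargs):
        """Build from an EDF file and a sidecar annotation CSV/JSON."""
        from .io import apply_montage, read_annotations, read_edf

        rec = read_edf(edf_path)
        if montage is not None:
            rec = apply_montage(rec, montage)
        rec.annotations = read_annotations(annotation_path)
        rec.__post_init__()
        return cls(rec, **kwargs)

    def fit(self, seed: int | None = None, epochs: int | None = None,
            progress: bool = False) -> "SeizureDetectionResults":
        """Run the full patient-specific pipeline and return the results."""
        tcfg = self.train_config
        if seed is not None or epochs is not None:
            tcfg = replace(tcfg,
                           seed=tcfg.seed if seed is None else seed,
                           epochs=tcfg.epochs if epochs is None else epochs)

        filtered = filter_recording(self.recording, keep_bands=self.keep_bands)
        split = build_training_set(filtered, self.plan)
        n_channels = filtered.n_channels
        del filtered  # the split holds copies of everything it needs

        ncfg = self.net_config or ModelConfig(
            n_channels=n_channels, n_samples=self.plan.T,
            seed=tcfg.seed)
        net = build_model(ncfg)
        history = train(net, split.train, tcfg, progress=progress)

        test_scores, test_truth = _score(net, split.test, self.plan.T)
        calib_scores, _ = _score(net, split.calibration, self.plan.T)
        train_scores, _ = _score(net, split.train_events_stream, self.plan.T)

        params = calibrate(calib_scores, train_scores,
                           split.train_event_intervals, self.grid)

        smoothed = maf_smooth(test_scores, params.N)
        pred_labels = collar_extend(binarize(smoothed, params.Thr), params.K)
        events = apply_pipeline(test_scores, params)

        test_hours = split.test.duration_s / 3600.0
        sens, spec, acc = segment_metrics(pred_labels, test_truth)
        esens, fdr, det, marked = event_metrics(events, split.test.annotations,
                                                test_hours)
        try:
            auroc = auroc_fixed_postproc(test_scores, test_truth)
        except ValueError:
            auroc = None
        report = MetricsReport(sens, spec, acc, esens, det, marked, fdr,
                               auroc, test_hours)
        return SeizureDetectionResults(
            model=self, network=net, net_config=ncfg, train_config=tcfg,
            split=split, history=history, postproc=params,
            test_scores=test_scores, test_truth=test_truth,
            predicted_labels=pred_labels, events=events, metrics=report,
        )


def _score(net: MCCHTSCCNet, rec: Recording, T: int):
    segs = label_segments(rec, T, T)
    scores = net.predict_proba(segs.X)
    return ScoreSequence(scores, T / rec.fs), segs.y


@dataclass
class SeizureDetectionResults:
    """Fit results: trained network, operating point, detections, metrics."""

    model: SeizureDetectionModel
    network: MCCHTSCCNet
    net_config: ModelConfig
    train_config: TrainConfig
    split: Split
    history: TrainHistory
    postproc: PostprocParams
    test_scores: ScoreSequence
    test_truth: np.ndarray
    predicted_labels: np.ndarray
    events: EventSet
    metrics: MetricsReport

    def score_recording(self, rec: Recording, prefiltered: bool = False):
        """Score any recording with the trained network.

        Returns ``(ScoreSequence, truth_labels)`` on non-overlapping 4 s
        windows; set ``prefiltered`` if ``rec`` already went through the
        DWT sub-band filter.
        """
        if not prefiltered:
            rec = filter_recording(rec, keep_bands=self.model.keep_bands)
        return _score(self.network, rec, self.model.plan.T)

    def detect(self, rec: Recording, prefiltered: bool = False) -> EventSet:
        """Detected seizure events in ``rec`` at the calibrated operating
        point."""
        seq, _ = self.score_recording(rec, prefiltered=prefiltered)
        return apply_pipeline(seq, self.postproc)

    def explain(self, segment: np.ndarray):
        """Branch-wise Grad-CAM heatmaps (list of branches, fused) for one
        (C, T) segment (prefiltered scale expected)."""
        return branch_maps(self.network, segment)

    def summary(self) -> str:
        total, breakdown = count_parameters(self.network)
        cos = sum(c for _, fam, c in breakdown if fam == "cosine")
        lines = [
            "Patient-specific seizure detection results",
            "==========================================",
            f"conv family          : {self.net_config.conv_family}",
            f"trainable parameters : {total}  ({cos} in cosine kernels)",
            f"training epochs      : {len(self.history.loss)}"
            f"  (final loss {self.history.loss[-1]:.4f},"
            f" acc {self.history.accuracy[-1]:.3f})",
            f"training events      : {len(self.split.train_event_intervals)}"
            f"  | test events: {len(self.split.test.annotations)}",
            f"operating point      : N={self.postproc.N}, "
            f"Thr={self.postproc.Thr:.2f}, K={self.postproc.K}",
            "",
            self.metrics.summary(),
        ]
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Plot the test score stream, threshold and detected events."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        d = self.test_scores.segment_duration_s
        t = self.test_scores.origin_s + np.arange(len(self.test_scores)) * d
        ax.plot(t / 3600.0, self.test_scores.scores, lw=0.5, label="score")
        ax.axhline(self.postproc.Thr, color="r", ls="--", lw=0.8, label="Thr")
        for ev in self.events:
            ax.axvspan(ev.onset_s / 3600.0, ev.offset_s / 3600.0,
                       color="orange", alpha=0.3)
        for iv in self.split.test.annotations:
            ax.axvspan(iv.onset_s / 3600.0, iv.offset_s / 3600.0,
                       color="green", alpha=0.2)
        ax.set_xlabel("test time (h)")
        ax.set_ylabel("seizure score")
        ax.legend(loc="upper right", fontsize=8)
        return ax


__all__ = ["SeizureDetectionModel", "SeizureDetectionResults"]
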