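"""Branch-wise Grad-CAM over the multiscale-convolution output.

Grad-CAM is computed with respect to the concatenated MCC feature map,
using the seizure-class logit (pre-softmax) as the target: channel weights
are the global average of the logit's gradient over a feature block, and
the raw map is the rectified weighted sum of the block's feature channels.
Because the three branches are concatenated width-wise, the map is split
sequentially into three contiguous blocks (floor(W/3) bins each, remainder
assigned to the last) to obtain per-branch explanations; each block map is
resized to the input sample axis by linear interpolation, and the fused
map is their pointwise mean.  Maps are max-normalized (an all-zero map
stays zero) — only relative attention is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SeizureInterval
from .nn.network import MCCHTSCCNet


class GraphError(RuntimeError):
    pass


@dataclass
class Heatmap:
    values: np.ndarray     # (n_bins,) in [0, 1]
    source: str            # 'branch0'.. or 'fused'
    samples_per_bin: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.max() > 0:
            if not (0.0 <= self.values.min() and self.values.max() <= 1.0 + 1e-12):
                raise ValueError("heatmap values must lie in [0, 1]")


def _normalize(v: np.ndarray) -> np.ndarray:
    peak = v.max() if v.size else 0.0
    return v / peak if peak > 0 else v


def mcc_activation_and_gradient(model: MCCHTSCCNet, segment: np.ndarray,
                                target_class: int = 1):
    """Forward one segment in evaluation mode and backpropagate the target
    logit to the MCC output; returns ``(features, gradient)`` both shaped
    ``(channels, width)``."""
    seg = np.asarray(segment, dtype=model.dtype)
    if seg.ndim != 2:
        raise ValueError("expected one (C, T) segment")
    logits = model.forward_logits(seg[None], training=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    model.zero_grad()
    model.backward(dlogits)
    feat = model.mcc_output[0, :, 0, :]
    grad = model.mcc_output_grad[0, :, 0, :]
    return np.asarray(feat, dtype=float), np.asarray(grad, dtype=float)


def gradcam_map(model: MCCHTSCCNet, segment: np.ndarray,
                target_class: int = 1) -> np.ndarray:
    """Raw (unnormalized, rectified) Grad-CAM map over the full MCC width."""
    feat, grad = mcc_activation_and_gradient(model, segment, target_class)
    weights = grad.mean(axis=1)  # global average pooling of the gradient
    return np.maximum((weights[:, None] * feat).sum(axis=0), 0.0)


def split_widths(W: int, n_blocks: int = 3) -> list[int]:
    """Sequential equal-width split: floor(W/n) per block, remainder to the
    last block."""
    if W < n_blocks:
        raise ValueError(f"cannot split width {W} into {n_blocks} blocks")
    base = W // n_blocks
    return [base] * (n_blocks - 1) + [W - base * (n_blocks - 1)]


def _resize(values: np.ndarray, n_out: int) -> np.ndarray:
    """Linear interpolation from bin centers onto an ``n_out``-sample axis."""
    n = values.size
    if n == 1:
        return np.full(n_out, values[0])
    src = (np.arange(n) + 0.5) / n
    dst = (np.arange(n_out) + 0.5) / n_out
    return np.interp(dst, src, values)


def branch_maps(model: MCCHTSCCNet, segment: np.ndarray,
                target_class: int = 1) -> tuple[list[Heatmap], Heatmap]:
    """Per-branch Grad-CAM heatmaps plus the fused map, all on the input
    sample axis."""
    if model.cfg.mcc.concat_axis != "time":
        raise GraphError("branch-wise Grad-CAM requires width-wise concat")
    feat, grad = mcc_activation_and_gradient(model, segment, target_class)
    W = feat.shape[1]
    n_branches = len(model.cfg.mcc.branch_kernel_lengths)
    widths = split_widths(W, n_branches)
    T = model.cfg.n_samples

    maps: list[Heatmap] = []
    resized = []
    start = 0
    for b, w in enumerate(widths):
        fblk = feat[:, start : start + w]
        gblk = grad[:, start : start + w]
        weights = gblk.mean(axis=1)
        raw = np.maximum((weights[:, None] * fblk).sum(axis=0), 0.0)
        up = _resize(raw, T)
        resized.append(up)
        maps.append(Heatmap(_normalize(up), f"branch{b}", 1.0))
        start += w
    fused = Heatmap(_normalize(np.mean(resized, axis=0)), "fused", 1.0)
    return maps, fused


def heatmap_locality_ratio(
    heatmap: Heatmap,
    segment_start_s: float,
    fs: float,
    annotations: list[SeizureInterval],
) -> float:
    """Mean heatmap value inside annotated spans over the mean outside.

    Returns NaN when the segment lies entirely inside or entirely outside
    the annotated spans (no contrast to measure).
    """
    n = heatmap.values.size
    t = segment_start_s + (np.arange(n) + 0.5) / fs * heatmap.samples_per_bin
    inside = np.zeros(n, dtype=bool)
    for iv in annotations:
        inside |= (t >= iv.onset_s) & (t < iv.offset_s)
    if inside.all() or not inside.any():
        return float("nan")
    outside_mean = heatmap.values[~inside].mean()
    inside_mean = heatmap.values[inside].mean()
    if outside_mean == 0:
        return float("inf") if inside_mean > 0 else float("nan")
    return float(inside_mean / outside_mean)


__all__ = [
    "GraphError",
    "Heatmap",
    "mcc_activation_and_gradient",
    "gradcam_map",
    "split_widths",
    "branch_maps",
    "heatmap_locality_ratio",
]
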