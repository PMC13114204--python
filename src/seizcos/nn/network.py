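"""The multiscale cosine-convolution seizure classifier.

Architecture (defaults):

* **MCC module** — three parallel branches with temporal cosine kernels of
  length 9, 5 and 1 (32 filters each).  Per branch: temporal conv (shared
  across electrodes) -> standard spatial conv spanning all electrodes ->
  batch normalization -> dropout -> max pooling.  Branch outputs are
  concatenated width-wise (along the pooled time axis) by default.
* **HTSCC modules** (x2) — a heterogeneous two-stream block: a shallow
  stream of one cosine conv (k=3, no normalization or regularization) and a
  deep stream of two cosine convs (k=3), each followed by layer
  normalization and spatial dropout; streams merged by channel
  concatenation (or addition).
* **Classifier head** — flatten -> dense hidden layer (ReLU) -> dense ->
  softmax over {interictal, ictal}.

Temporal convolutions may be built cosine-parameterized (2 parameters per
kernel slot) or standard (k parameters per slot); the spatial convolution
in the MCC module is always standard.  Stream convolutions inside HTSCC
use zero-padded "same" convolution so the two streams stay width-aligned
for merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .layers import (
    BatchNorm, CosineConv, Dense, Dropout, Flatten, LayerNorm, MaxPool,
    Module, ReLU, Sequential, ShapeError, SpatialConv, SpatialDropout,
    StandardConv, softmax,
)


@dataclass
class MCCConfig:
    branch_kernel_lengths: tuple[int, ...] = (9, 5, 1)
    filters_per_branch: int = 32
    pool_size: int = 12
    pool_stride: int = 12
    dropout_rate: float = 0.5
    concat_axis: str = "time"  # 'time' | 'channel'

    def __post_init__(self):
        if not self.branch_kernel_lengths:
            raise ValueError("need at least one branch")
        if any(k < 1 for k in self.branch_kernel_lengths):
            raise ValueError("kernel lengths must be >= 1")
        if self.concat_axis not in ("time", "channel"):
            raise ValueError("concat_axis must be 'time' or 'channel'")


@dataclass
class HTSCCConfig:
    kernel_length: int = 3
    channels: int = 32
    deep_layers: int = 2
    spatial_dropout_rate: float = 0.25
    merge: str = "concat_channels"  # 'concat_channels' | 'add'

    def __post_init__(self):
        if self.kernel_length < 1:
            raise ValueError("kernel length must be >= 1")
        if self.merge not in ("concat_channels", "add"):
            raise ValueError("merge must be 'concat_channels' or 'add'")


@dataclass
class ModelConfig:
    n_channels: int = 18
    n_samples: int = 1024
    mcc: MCCConfig = field(default_factory=MCCConfig)
    n_htscc_modules: int = 2
    htscc: HTSCCConfig = field(default_factory=HTSCCConfig)
    fc_hidden: int = 64
    n_classes: int = 2
    conv_family: str = "cosine"  # temporal conv family; spatial always standard
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        if self.conv_family not in ("cosine", "standard"):
            raise ValueError("conv_family must be 'cosine' or 'standard'")
        if self.n_htscc_modules < 0:
            raise ValueError("n_htscc_modules must be >= 0")

    def with_family(self, family: str) -> "ModelConfig":
        return replace(self, conv_family=family)


def _temporal_conv(family, in_ch, out_ch, k, padding, rng, dtype):
    cls = CosineConv if family == "cosine" else StandardConv
    return cls(in_ch, out_ch, k, padding=padding, rng=rng, dtype=dtype)


class MCCBlock(Module):
    """Parallel multiscale branches with concatenated outputs."""

    def __init__(self, cfg: MCCConfig, n_electrodes: int, n_samples: int,
                 family: str, rng, dtype):
        super().__init__()
        self.cfg = cfg
        self.branches = []
        self.branch_widths = []
        f = cfg.filters_per_branch
        for k in cfg.branch_kernel_lengths:
            conv_w = n_samples - k + 1
            if conv_w < cfg.pool_size:
                raise ShapeError(f"branch k={k}: input too short to pool")
            pooled_w = (conv_w - cfg.pool_size) // cfg.pool_stride + 1
            tconv = _temporal_conv(family, 1, f, k, "valid", rng, dtype)
            tconv.compute_input_grad = False  # raw-EEG input needs no gradient
            self.branches.append(Sequential([
                tconv,
                SpatialConv(f, f, n_electrodes, rng=rng, dtype=dtype),
                BatchNorm(f, dtype=dtype),
                Dropout(cfg.dropout_rate),
                MaxPool(cfg.pool_size, cfg.pool_stride),
            ]))
            self.branch_widths.append(pooled_w)
        if cfg.concat_axis == "channel" and len(set(self.branch_widths)) > 1:
            raise ShapeError("channel concat requires equal branch widths")
        self.out_channels = f * (len(self.branches) if cfg.concat_axis == "channel" else 1)
        self.out_width = (self.branch_widths[0] if cfg.concat_axis == "channel"
                          else sum(self.branch_widths))

    def submodules(self):
        yield from self.branches

    def forward(self, x, training=False, rng=None):
        outs = [b.forward(x, training=training, rng=rng) for b in self.branches]
        axis = 1 if self.cfg.concat_axis == "channel" else 3
        self._split = [o.shape[axis] for o in outs]
        return np.concatenate(outs, axis=axis)

    def backward(self, grad):
        axis = 1 if self.cfg.concat_axis == "channel" else 3
        pieces = np.split(grad, np.cumsum(self._split)[:-1], axis=axis)
        dxs = [b.backward(g) for b, g in zip(self.branches, pieces)]
        if any(dx is None for dx in dxs):
            return None
        return sum(dxs)

    def zero_grad(self):
        for b in self.branches:
            b.zero_grad()

    def n_params(self):
        return sum(b.n_params() for b in self.branches)


class HTSCCBlock(Module):
    """Heterogeneous two-stream block (shallow + deep cosine streams)."""

    def __init__(self, cfg: HTSCCConfig, in_channels: int, family: str, rng, dtype):
        super().__init__()
        self.cfg = cfg
        k = cfg.kernel_length
        ch = cfg.channels
        self.shallow = Sequential([
            _temporal_conv(family, in_channels, ch, k, "same", rng, dtype),
        ])
        deep = []
        prev = in_channels
        for _ in range(cfg.deep_layers):
            deep += [
                _temporal_conv(family, prev, ch, k, "same", rng, dtype),
                LayerNorm(ch, dtype=dtype),
                SpatialDropout(cfg.spatial_dropout_rate),
            ]
            prev = ch
        self.deep = Sequential(deep)
        self.out_channels = 2 * ch if cfg.merge == "concat_channels" else ch

    def submodules(self):
        yield self.shallow
        yield self.deep

    def forward(self, x, training=False, rng=None):
        s = self.shallow.forward(x, training=training, rng=rng)
        d = self.deep.forward(x, training=training, rng=rng)
        if self.cfg.merge == "add":
            if s.shape != d.shape:
                raise ShapeError(
                    f"merge='add' needs equal stream shapes, got {s.shape} vs {d.shape}")
            return s + d
        self._ch = s.shape[1]
        return np.concatenate([s, d], axis=1)

    def backward(self, grad):
        if self.cfg.merge == "add":
            gs, gd = grad, grad
        else:
            gs, gd = grad[:, : self._ch], grad[:, self._ch :]
        return self.shallow.backward(gs) + self.deep.backward(gd)

    def zero_grad(self):
        self.shallow.zero_grad()
        self.deep.zero_grad()

    def n_params(self):
        return self.shallow.n_params() + self.deep.n_params()


class MCCHTSCCNet(Module):
    """Full classifier: MCC -> n x HTSCC -> dense head -> softmax.

    ``forward`` caches the MCC concatenated output and (after ``backward``)
    the gradient flowing into it, which is what Grad-CAM consumes.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        self.mcc = MCCBlock(cfg.mcc, cfg.n_channels, cfg.n_samples,
                            cfg.conv_family, rng, dtype)
        self.htsccs = []
        ch = self.mcc.out_channels
        for _ in range(cfg.n_htscc_modules):
            blk = HTSCCBlock(cfg.htscc, ch, cfg.conv_family, rng, dtype)
            self.htsccs.append(blk)
            ch = blk.out_channels
        fc_in = ch * self.mcc.out_width
        self.head = Sequential([
            Flatten(),
            Dense(fc_in, cfg.fc_hidden, rng=rng, dtype=dtype),
            ReLU(),
            Dense(cfg.fc_hidden, cfg.n_classes, rng=rng, dtype=dtype),
        ])
        self.dtype = dtype

    def submodules(self):
        yield self.mcc
        yield from self.htsccs
        yield self.head

    # -- forward/backward -------------------------------------------------
    def forward_logits(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]  # (B, 1, C, T)
        if x.shape[2] != self.cfg.n_channels or x.shape[3] != self.cfg.n_samples:
            raise ShapeError(
                f"expected (C={self.cfg.n_channels}, T={self.cfg.n_samples}) "
                f"segments, got {x.shape[2:]}"
            )
        h = self.mcc.forward(x, training=training, rng=rng)
        self.mcc_output = h
        for blk in self.htsccs:
            h = blk.forward(h, training=training, rng=rng)
        return self.head.forward(h, training=training, rng=rng)

    def forward(self, x, training=False, rng=None):
        return softmax(self.forward_logits(x, training=training, rng=rng))

    def backward(self, dlogits):
        g = self.head.backward(dlogits)
        for blk in reversed(self.htsccs):
            g = blk.backward(g)
        self.mcc_output_grad = g
        return self.mcc.backward(g)

    def zero_grad(self):
        self.mcc.zero_grad()
        for blk in self.htsccs:
            blk.zero_grad()
        self.head.zero_grad()

    # -- inference helpers -------------------------------------------------
    def predict_proba(self, X, batch_size: int = 128) -> np.ndarray:
        """Seizure-class probabilities for an (n, C, T) stack, batched."""
        X = np.asarray(X)
        out = np.empty(len(X))
        for i in range(0, len(X), batch_size):
            out[i : i + batch_size] = self.forward(X[i : i + batch_size])[:, 1]
        return out

    def n_params(self):
        return sum(m.n_params() for m in self.submodules())


def build_mcc(cfg: MCCConfig, n_electrodes: int = 18, n_samples: int = 1024,
              family: str = "cosine", seed: int = 0,
              dtype: str = "float32") -> MCCBlock:
    rng = np.random.default_rng(seed)
    return MCCBlock(cfg, n_electrodes, n_samples, family, rng, np.dtype(dtype).type)


def build_htscc(cfg: HTSCCConfig, in_channels: int = 32, family: str = "cosine",
                seed: int = 0, dtype: str = "float32") -> HTSCCBlock:
    rng = np.random.default_rng(seed)
    return HTSCCBlock(cfg, in_channels, family, rng, np.dtype(dtype).type)


def build_model(cfg: ModelConfig) -> MCCHTSCCNet:
    return MCCHTSCCNet(cfg)


def count_parameters(model: Module) -> tuple[int, list[tuple[str, str, int]]]:
    """Total trainable scalar count plus a per-layer breakdown.

    Returns ``(total, [(layer_name, family, count), ...])``; ``family`` is
    'cosine', 'standard' or '-' for non-convolutional layers.
    """
    breakdown: list[tuple[str, str, int]] = []

    def walk(mod: Module, prefix: str):
        subs = list(mod.submodules())
        if not subs:
            if mod.params:
                breakdown.append(
                    (f"{prefix}{type(mod).__name__}", mod.family or "-",
                     mod.n_params()))
            return
        for i, sub in enumerate(subs):
            walk(sub, f"{prefix}{i}.")

    walk(model, "")
    total = sum(c for _, _, c in breakdown)
    return total, breakdown


__all__ = [
    "MCCConfig", "HTSCCConfig", "ModelConfig",
    "MCCBlock", "HTSCCBlock", "MCCHTSCCNet",
    "build_mcc", "build_htscc", "build_model", "count_parameters",
]
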