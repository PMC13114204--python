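"""Minimal numpy layer stack with hand-written backward passes.

Feature maps use the layout ``(batch, features, electrodes, width)``; the
electrode axis is collapsed to 1 by the spatial convolution and kept for
shape uniformity afterwards.  Every layer caches what its backward pass
needs during ``forward`` and accumulates parameter gradients in
``self.grads`` during ``backward``, returning the gradient with respect to
its input.  Stochastic layers (dropout) draw from the generator passed to
``forward`` and are identity when ``training`` is false.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ShapeError(ValueError):
    pass


class Module:
    """Base class: named parameters, gradients, and a conv-family tag."""

    family: str | None = None  # 'cosine' | 'standard' | None

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, training=False, rng=None):
        return self.forward(x, training=training, rng=rng)

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def submodules(self):
        yield from ()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.params.items():
            yield (f"{prefix}{k}", v)
        for i, m in enumerate(self.submodules()):
            yield from m.named_parameters(f"{prefix}{i}.{type(m).__name__}.")


class Sequential(Module):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def submodules(self):
        yield from self.layers

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def n_params(self):
        return sum(layer.n_params() for layer in self.layers)


# ---------------------------------------------------------------------------
# convolutions

def _conv_windows(x: np.ndarray, k: int) -> np.ndarray:
    # (B, F, E, W) -> (B, F, E, W-k+1, k)
    return sliding_window_view(x, k, axis=3)


class _TemporalConv(Module):
    """1-D convolution along the time axis, shared across electrodes.

    ``padding='valid'`` shrinks the width by k-1; ``'same'`` zero-pads so the
    output width equals the input width.  The kernel is supplied by the
    subclass through :meth:`kernel`, and gradients with respect to the
    materialized kernel are routed back through :meth:`kernel_backward`.
    """

    def __init__(self, in_channels, out_channels, k, padding="valid"):
        super().__init__()
        if k < 1:
            raise ValueError("kernel length must be >= 1")
        if padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.k = int(k)
        self.padding = padding
        # first-layer convs can skip the (large) input-gradient computation
        self.compute_input_grad = True

    def kernel(self) -> np.ndarray:  # (out, in, k)
        raise NotImplementedError

    def kernel_backward(self, d_kernel: np.ndarray) -> None:
        raise NotImplementedError

    def _pads(self):
        return ((self.k - 1) // 2, self.k // 2) if self.padding == "same" else (0, 0)

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.in_channels:
            raise ShapeError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        pl, pr = self._pads()
        if pl or pr:
            x = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        if x.shape[3] < self.k:
            raise ShapeError("input narrower than kernel")
        win = _conv_windows(x, self.k)
        self._win = win
        out = np.einsum("biewk,oik->boew", win, self.kernel(), optimize=True)
        return out

    def backward(self, grad):
        Wk = self.kernel()
        d_kernel = np.einsum("boew,biewk->oik", grad, self._win, optimize=True)
        self.kernel_backward(d_kernel)
        if not self.compute_input_grad:
            return None
        gpad = np.pad(grad, ((0, 0), (0, 0), (0, 0), (self.k - 1, self.k - 1)))
        gwin = _conv_windows(gpad, self.k)
        dx = np.einsum("boewk,oik->biew", gwin, Wk[:, :, ::-1], optimize=True)
        pl, pr = self._pads()
        if pl or pr:
            dx = dx[:, :, :, pl : dx.shape[3] - pr]
        return dx


class StandardConv(_TemporalConv):
    """Ordinary temporal convolution with k free weights per kernel slot."""

    family = "standard"

    def __init__(self, in_channels, out_channels, k, padding="valid",
                 rng=None, dtype=np.float64):
        super().__init__(in_channels, out_channels, k, padding)
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(in_channels * k)
        self.params["weight"] = (scale * rng.standard_normal(
            (out_channels, in_channels, k))).astype(dtype)
        self.zero_grad()

    def kernel(self):
        return self.params["weight"]

    def kernel_backward(self, d_kernel):
        self.grads["weight"] += d_kernel


class CosineConv(_TemporalConv):
    """Cosine-parameterized temporal convolution.

    Each (out, in) kernel slot holds two learnable scalars, amplitude ``A``
    and angular frequency ``omega``; the k coefficients are
    ``A * cos(omega * (m - (k-1)/2))`` for m = 0..k-1.  The kernel is
    center-symmetric, so convolution and cross-correlation coincide.
    Both parameters are initialized from N(0, 1).
    """

    family = "cosine"

    def __init__(self, in_channels, out_channels, k, padding="valid",
                 rng=None, dtype=np.float64):
        super().__init__(in_channels, out_channels, k, padding)
        rng = rng or np.random.default_rng(0)
        self.params["A"] = rng.standard_normal((out_channels, in_channels)).astype(dtype)
        self.params["omega"] = rng.standard_normal((out_channels, in_channels)).astype(dtype)
        self.offsets = (np.arange(k) - (k - 1) / 2.0).astype(dtype)
        self.zero_grad()

    def kernel(self):
        phase = self.params["omega"][..., None] * self.offsets
        return self.params["A"][..., None] * np.cos(phase)

    def kernel_backward(self, d_kernel):
        phase = self.params["omega"][..., None] * self.offsets
        self.grads["A"] += (d_kernel * np.cos(phase)).sum(axis=-1)
        self.grads["omega"] += (
            d_kernel * self.params["A"][..., None] * (-self.offsets) * np.sin(phase)
        ).sum(axis=-1)


class SpatialConv(Module):
    """Standard convolution spanning the full electrode axis (C x 1 kernel),
    collapsing it to a single row."""

    family = "standard"

    def __init__(self, in_channels, out_channels, n_electrodes,
                 rng=None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(in_channels * n_electrodes)
        self.n_electrodes = int(n_electrodes)
        self.params["weight"] = (scale * rng.standard_normal(
            (out_channels, in_channels, n_electrodes))).astype(dtype)
        self.zero_grad()

    def forward(self, x, training=False, rng=None):
        if x.shape[2] != self.n_electrodes:
            raise ShapeError(
                f"expected {self.n_electrodes} electrodes, got {x.shape[2]}")
        self._x = x
        out = np.einsum("biew,oie->bow", x, self.params["weight"], optimize=True)
        return out[:, :, None, :]

    def backward(self, grad):
        g = grad[:, :, 0, :]
        self.grads["weight"] += np.einsum("bow,biew->oie", g, self._x, optimize=True)
        return np.einsum("bow,oie->biew", g, self.params["weight"], optimize=True)


# ---------------------------------------------------------------------------
# normalization / regularization / pooling

class BatchNorm(Module):
    """Per-feature-channel batch normalization with running statistics."""

    def __init__(self, n_channels, momentum=0.1, eps=1e-5, dtype=np.float64):
        super().__init__()
        self.params["gamma"] = np.ones(n_channels, dtype=dtype)
        self.params["beta"] = np.zeros(n_channels, dtype=dtype)
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.zero_grad()

    @staticmethod
    def _b(v):  # broadcast (F,) over (B, F, E, W)
        return v[None, :, None, None]

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._b(mean)) * self._b(inv)
        self._cache = (xhat, inv, training, x.shape)
        return self._b(self.params["gamma"]) * xhat + self._b(self.params["beta"])

    def backward(self, grad):
        xhat, inv, training, shape = self._cache
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self._b(self.params["gamma"])
        if not training:
            return gxhat * self._b(inv)
        n = shape[0] * shape[2] * shape[3]
        sum_g = gxhat.sum(axis=(0, 2, 3))
        sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3))
        return self._b(inv) / n * (
            n * gxhat - self._b(sum_g) - xhat * self._b(sum_gx)
        )


class LayerNorm(Module):
    """Per-sample normalization over all non-batch axes, with a per-channel
    affine transform."""

    def __init__(self, n_channels, eps=1e-5, dtype=np.float64):
        super().__init__()
        self.params["gamma"] = np.ones(n_channels, dtype=dtype)
        self.params["beta"] = np.zeros(n_channels, dtype=dtype)
        self.eps = eps
        self.zero_grad()

    @staticmethod
    def _b(v):
        return v[None, :, None, None]

    def forward(self, x, training=False, rng=None):
        mean = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self._b(self.params["gamma"]) * xhat + self._b(self.params["beta"])

    def backward(self, grad):
        xhat, inv = self._cache
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self._b(self.params["gamma"])
        n = xhat[0].size
        sum_g = gxhat.sum(axis=(1, 2, 3), keepdims=True)
        sum_gx = (gxhat * xhat).sum(axis=(1, 2, 3), keepdims=True)
        return inv / n * (n * gxhat - sum_g - xhat * sum_gx)


class Dropout(Module):
    def __init__(self, rate):
        super().__init__()
        self.rate = float(rate)

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class SpatialDropout(Dropout):
    """Dropout of whole feature channels (one mask value per (batch, channel))."""

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        m = (rng.random(x.shape[:2]) >= self.rate) / (1.0 - self.rate)
        self._mask = m[:, :, None, None]
        return x * self._mask


class MaxPool(Module):
    """Max pooling along the time axis (trailing partial window dropped)."""

    def __init__(self, size, stride=None):
        super().__init__()
        self.size = int(size)
        self.stride = int(stride or size)

    def forward(self, x, training=False, rng=None):
        if x.shape[3] < self.size:
            raise ShapeError("input narrower than pooling window")
        win = sliding_window_view(x, self.size, axis=3)[:, :, :, :: self.stride, :]
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, grad):
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        b, f, e, w = np.indices(grad.shape)
        np.add.at(dx, (b, f, e, w * self.stride + self._arg), grad)
        return dx


class ReLU(Module):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Module):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Module):
    def __init__(self, in_features, out_features, rng=None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(in_features)
        self.params["weight"] = (scale * rng.standard_normal(
            (out_features, in_features))).astype(dtype)
        self.params["bias"] = np.zeros(out_features, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, grad):
        self.grads["weight"] += grad.T @ self._x
        self.grads["bias"] += grad.sum(axis=0)
        return grad @ self.params["weight"]


# ---------------------------------------------------------------------------
# loss

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = len(labels)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


__all__ = [
    "Module", "Sequential", "ShapeError",
    "StandardConv", "CosineConv", "SpatialConv",
    "BatchNorm", "LayerNorm", "Dropout", "SpatialDropout",
    "MaxPool", "ReLU", "Flatten", "Dense",
    "softmax", "cross_entropy",
]
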