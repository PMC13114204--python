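"""The cosine kernel parameterization and its parameter accounting.

A length-k convolution kernel is generated from two scalars, amplitude
``A`` and angular frequency ``omega`` (radians per sample):

    K[m] = A * cos(omega * (m - (k - 1) / 2)),   m = 0, ..., k-1.

The kernel is symmetric about its center, so convolving with it equals
cross-correlating with it, and each kernel slot costs 2 learnable
parameters instead of k — a reduction ratio of (k - 2) / k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import CosineConv


def kernel_from_params(A: float, omega: float, k: int) -> np.ndarray:
    """Materialize the length-``k`` cosine kernel for ``(A, omega)``."""
    if k < 1:
        raise ValueError("kernel length must be >= 1")
    m = np.arange(k, dtype=float)
    return A * np.cos(omega * (m - (k - 1) / 2.0))


def init_params(n_kernels: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n_kernels`` independent ``(A, omega)`` pairs from N(0, 1).

    Returns an ``(n_kernels, 2)`` array; reproducible for a given seed.
    """
    if n_kernels < 1:
        raise ValueError("need at least one kernel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((n_kernels, 2))


@dataclass(frozen=True)
class CosineConvSpec:
    """Shape of a cosine convolution layer: one (A, omega) pair per
    (out_channel, in_channel) slot."""

    in_channels: int
    out_channels: int
    k: int
    use_bias: bool = False

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.k < 1:
            raise ValueError("kernel length must be >= 1")

    @property
    def slots(self) -> int:
        return self.in_channels * self.out_channels


def parameter_count(spec: CosineConvSpec) -> int:
    """Learnable scalars in a cosine layer: 2 per slot (+ bias per output)."""
    n = 2 * spec.slots
    return n + spec.out_channels if spec.use_bias else n


def standard_parameter_count(spec: CosineConvSpec) -> int:
    """Learnable scalars in the standard convolution of the same shape."""
    n = spec.k * spec.slots
    return n + spec.out_channels if spec.use_bias else n


def reduction_ratio(k: int) -> float:
    """Per-kernel parameter reduction of cosine vs standard: (k - 2) / k."""
    return (k - 2) / k


def cosine_conv_forward(x: np.ndarray, spec: CosineConvSpec,
                        params: np.ndarray) -> np.ndarray:
    """Functional forward pass of a cosine convolution layer.

    Parameters
    ----------
    x : ``(in_channels, L)`` or ``(batch, in_channels, L)`` input map
    spec : layer shape
    params : ``(out_channels, in_channels, 2)`` array of (A, omega) pairs

    Returns the valid cross-correlation, ``(out_channels, L - k + 1)``
    (batched if the input was batched).
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.out_channels, spec.in_channels, 2):
        raise ValueError(
            f"params shape {params.shape} does not match spec "
            f"({spec.out_channels}, {spec.in_channels}, 2)")
    x = np.asarray(x, dtype=float)
    batched = x.ndim == 3
    if not batched:
        x = x[None]
    if x.shape[1] != spec.in_channels:
        raise ValueError("input channel count does not match spec")
    if x.shape[2] < spec.k:
        raise ValueError("input shorter than kernel")
    layer = CosineConv(spec.in_channels, spec.out_channels, spec.k)
    layer.params["A"] = params[..., 0]
    layer.params["omega"] = params[..., 1]
    out = layer.forward(x[:, :, None, :])[:, :, 0, :]
    return out if batched else out[0]


__all__ = [
    "CosineConvSpec",
    "kernel_from_params",
    "init_params",
    "parameter_count",
    "standard_parameter_count",
    "reduction_ratio",
    "cosine_conv_forward",
]
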