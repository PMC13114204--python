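"""Adam optimizer over the layer stack's named parameters."""

from __future__ import annotations

import numpy as np

from .layers import Module


def _walk(module: Module, prefix=""):
    subs = list(module.submodules())
    if not subs:
        for k in module.params:
            yield f"{prefix}{k}", module, k
        return
    for i, sub in enumerate(subs):
        yield from _walk(sub, f"{prefix}{i}.")


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, model: Module, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(mod.params[key])
                  for name, mod, key in _walk(model)}
        self.v = {name: np.zeros_like(mod.params[key])
                  for name, mod, key in _walk(model)}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, mod, key in _walk(self.model):
            g = mod.grads[key]
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            mod.params[key] = mod.params[key] - lr * mhat / (np.sqrt(vhat) + self.eps)


def parameter_checksum(model: Module) -> float:
    """Order-stable scalar digest of all parameters (for determinism tests)."""
    return float(sum(np.sum(np.abs(mod.params[key]))
                     for _, mod, key in _walk(model)))


__all__ = ["Adam", "parameter_checksum"]
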