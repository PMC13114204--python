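"""Model checkpoints: named parameter tensors + a JSON config header."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn.layers import BatchNorm, Module
from .nn.network import HTSCCConfig, MCCConfig, MCCHTSCCNet, ModelConfig

_BUFFERS = ("running_mean", "running_var")


def _leaves(module: Module, prefix=""):
    subs = list(module.submodules())
    if not subs:
        yield prefix, module
        return
    for i, sub in enumerate(subs):
        yield from _leaves(sub, f"{prefix}{i}.")


def config_to_dict(cfg: ModelConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["mcc"] = MCCConfig(**{**d["mcc"],
                            "branch_kernel_lengths": tuple(d["mcc"]["branch_kernel_lengths"])})
    d["htscc"] = HTSCCConfig(**d["htscc"])
    return ModelConfig(**d)


def save_model(net: MCCHTSCCNet, path: str | Path) -> None:
    arrays = {}
    for name, leaf in _leaves(net):
        for key, val in leaf.params.items():
            arrays[f"{name}{type(leaf).__name__}.{key}"] = val
        if isinstance(leaf, BatchNorm):
            for key in _BUFFERS:
                arrays[f"{name}{type(leaf).__name__}.{key}"] = getattr(leaf, key)
    arrays["__config__"] = np.frombuffer(
        json.dumps(config_to_dict(net.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> MCCHTSCCNet:
    with np.load(path) as data:
        cfg = config_from_dict(json.loads(bytes(data["__config__"]).decode()))
        net = MCCHTSCCNet(cfg)
        for name, leaf in _leaves(net):
            for key in leaf.params:
                leaf.params[key] = data[f"{name}{type(leaf).__name__}.{key}"].copy()
            if isinstance(leaf, BatchNorm):
                for key in _BUFFERS:
                    setattr(leaf, key,
                            data[f"{name}{type(leaf).__name__}.{key}"].copy())
            leaf.zero_grad()
    return net


__all__ = ["save_model", "load_model", "config_to_dict", "config_from_dict"]
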