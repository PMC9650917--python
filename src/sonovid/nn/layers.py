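"""Layer/module abstractions: parameter registry, Linear, Conv2d, GroupNorm."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Parameter", "Module", "Linear", "Conv2d", "GroupNorm", "Sequential", "group_normalize"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery and state (de)serialization."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} vs model {p.data.shape}"
                )
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.swapaxes(0, 1)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        bias: bool = False,
        zero_init: bool = False,
    ):
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        shape = (out_channels, in_channels, kernel_size, kernel_size)
        if zero_init:
            w = np.zeros(shape, dtype=np.float32)
        else:
            # He initialization, suited to ReLU nets
            w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


def group_normalize(x: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Standardize (N,C,H,W) per sample within channel groups (pre-affine)."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"groups={groups} does not divide channels={c}")
    xg = x.reshape(n, groups, c // groups * h * w)
    mu = xg.mean(axis=2, keepdims=True)
    centered = xg - mu
    var = (centered * centered).mean(axis=2, keepdims=True)
    out = centered * ((var + eps) ** -0.5)
    return out.reshape(n, c, h, w)


class GroupNorm(Module):
    """Group normalization with learned per-channel affine (batch-size independent)."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError(f"groups={groups} does not divide channels={channels}")
        self.groups = groups
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        out = group_normalize(x, self.groups, self.eps)
        return out * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.items = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x
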