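"""Optimizers (momentum SGD, LARS) and the cosine-annealing schedule."""

from __future__ import annotations

import math

import numpy as np

from .layers import Parameter

__all__ = ["SGD", "LARS", "cosine_annealing_lr"]


def cosine_annealing_lr(base_lr: float, epoch: int, total_epochs: int, eta_min: float = 0.0) -> float:
    """eta_t = eta_min + 1/2 (eta_0 - eta_min)(1 + cos(pi t / T_max))."""
    if total_epochs <= 1:
        return base_lr
    t = min(epoch, total_epochs - 1)
    return eta_min + 0.5 * (base_lr - eta_min) * (1.0 + math.cos(math.pi * t / (total_epochs - 1)))


class SGD:
    """Stochastic gradient descent with momentum and decoupled-from-nothing
    (classic, loss-coupled) weight decay."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"velocity": [v.copy() for v in self._velocity], "lr": self.lr}

    def load_state_dict(self, state: dict) -> None:
        self._velocity = [np.asarray(v, dtype=np.float32).copy() for v in state["velocity"]]


class LARS:
    """Layer-wise adaptive rate scaling over momentum SGD.

    Each parameter tensor is treated as one layer; the raw gradient is scaled
    by the trust ratio ``||w|| / (||g|| + wd * ||w||)``. One-dimensional
    parameters (biases, normalization affines) are excluded from both
    adaptation and weight decay, following common practice for this optimizer.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
        trust_coefficient: float = 0.001,
        eps: float = 1e-9,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.trust_coefficient = trust_coefficient
        self.eps = eps
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            adapt = p.data.ndim > 1
            if adapt and self.weight_decay:
                g = g + self.weight_decay * p.data
            if adapt:
                w_norm = float(np.linalg.norm(p.data))
                g_norm = float(np.linalg.norm(g))
                if w_norm > 0 and g_norm > 0:
                    g = g * (self.trust_coefficient * w_norm / (g_norm + self.eps))
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"velocity": [v.copy() for v in self._velocity], "lr": self.lr}

    def load_state_dict(self, state: dict) -> None:
        self._velocity = [np.asarray(v, dtype=np.float32).copy() for v in state["velocity"]]
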