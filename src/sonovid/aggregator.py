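"""Temporal aggregation by multi-meta attention.

Given per-frame features F^t (t = 1..T, each m-dimensional), a cascade of L
shared fully-connected layers with Tanh activations produces per-frame,
per-dimension attention logits e^t = E_L^t (E_0^t = F^t). A softmax across
the *frame* axis, taken independently for every feature dimension i, yields
a T×m attention matrix A with per-dimension columns summing to one, and the
video-level feature is the convex combination

    F_bar_i = sum_t A_i^t * F_i^t.

Because the softmax runs over frames, the operator accepts any sequence
length without reconfiguration and is invariant to frame order. With equal
logits it degrades to average pooling over frames; with ``final_activation
= "none"`` and sharply peaked logits it approaches per-dimension max
pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, as_tensor

__all__ = [
    "AttentionConfig",
    "MultiMetaAttention",
    "attention_logits",
    "attention_weights",
    "aggregate",
    "forward",
    "average_pool",
    "max_pool",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Cascade depth and activation of the attention scorer.

    All layer widths equal the feature dimension m; Tanh is the activation
    of every cascade layer. ``final_activation='none'`` drops the Tanh on
    the last layer, unbounding the logits (needed to realize the max-pooling
    limit; the bounded Tanh form is the default).
    """

    feature_dim: int
    num_layers: int = 2
    final_activation: str = "tanh"
    seed: int = 0

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.final_activation not in ("tanh", "none"):
            raise ValueError(f"final_activation must be 'tanh' or 'none', got {self.final_activation!r}")


class MultiMetaAttention(nn.Module):
    """Cascaded attention scorer + per-dimension softmax + weighted sum."""

    def __init__(self, config: AttentionConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        m = config.feature_dim
        self.layers = [nn.Linear(m, m, rng) for _ in range(config.num_layers)]

    def logits(self, features: Tensor) -> Tensor:
        """(..., T, m) -> (..., T, m); applied frame-wise with shared weights."""
        if features.shape[-1] != self.config.feature_dim:
            raise ValueError(
                f"feature width {features.shape[-1]} does not match configured m="
                f"{self.config.feature_dim}"
            )
        out = features
        last = len(self.layers) - 1
        for idx, layer in enumerate(self.layers):
            out = layer(out)
            if idx < last or self.config.final_activation == "tanh":
                out = out.tanh()
        return out

    def weights(self, logits: Tensor) -> Tensor:
        """Softmax over the frame axis (second to last), per feature dimension."""
        return F.softmax(logits, axis=-2)

    def forward(self, features: Tensor) -> Tensor:
        """(..., T, m) -> (..., m) attention-weighted aggregation."""
        att = self.weights(self.logits(features))
        return (att * features).sum(axis=-2)

    def zero_weights(self) -> None:
        """Zero the cascade (uniform attention → exact average pooling)."""
        for layer in self.layers:
            layer.weight.data[...] = 0.0
            if layer.bias is not None:
                layer.bias.data[...] = 0.0


# ------------------------------------------------- functional (NumPy) facade


def attention_logits(features: np.ndarray, module: MultiMetaAttention) -> np.ndarray:
    """Per-frame cascade logits of a (T, m) feature stack."""
    return module.logits(as_tensor(np.asarray(features, dtype=np.float32))).numpy()


def attention_weights(logits: np.ndarray) -> np.ndarray:
    """Per-dimension softmax across frames of (T, m) logits -> T×m attention
    matrix whose columns (over t) each sum to one."""
    logits = np.asarray(logits, dtype=np.float32)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("attention logits contain non-finite values")
    shifted = logits - logits.max(axis=-2, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-2, keepdims=True)


def aggregate(features: np.ndarray, attention: np.ndarray) -> np.ndarray:
    """F_bar_i = sum_t A_i^t F_i^t for (T, m) inputs -> (m,) output."""
    features = np.asarray(features, dtype=np.float32)
    attention = np.asarray(attention, dtype=np.float32)
    if features.shape != attention.shape:
        raise ValueError(f"shape mismatch: features {features.shape} vs attention {attention.shape}")
    return (attention * features).sum(axis=-2)


def forward(features: np.ndarray, module: MultiMetaAttention) -> np.ndarray:
    """Full composition logits -> softmax -> weighted sum on a (T, m) array."""
    return module(as_tensor(np.asarray(features, dtype=np.float32))).numpy()


def average_pool(features: np.ndarray) -> np.ndarray:
    """Degenerate baseline: uniform attention = arithmetic mean over frames."""
    return np.asarray(features, dtype=np.float32).mean(axis=-2)


def max_pool(features: np.ndarray) -> np.ndarray:
    """Extreme baseline: per-dimension maximum over frames."""
    return np.asarray(features, dtype=np.float32).max(axis=-2)
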