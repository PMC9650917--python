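"""Per-frame feature extractor: ResNet-18-style backbone with group
normalization and non-local self-attention blocks in stages 3 and 4.

The backbone maps one grayscale frame v_t to an m-dimensional feature
f_t = Theta(v_t). Group normalization replaces batch normalization
throughout because video batches are small and frames within a clip are
highly correlated, which destabilizes batch statistics. A non-local block
— each spatial position's response is a softmax-weighted sum of the features
at all positions, added residually — is inserted after the last residual
block of stages 3 and 4 to capture spatially distant relationships.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["EncoderConfig", "NonLocalBlock", "Encoder", "encode_frame", "encode_frames"]

MIN_INPUT_SIZE = 32


@dataclass(frozen=True)
class EncoderConfig:
    """Backbone hyperparameters. Feature width m = 8 * base_width."""

    in_channels: int = 1
    base_width: int = 64
    gn_groups: int = 32
    nl_stages: tuple[int, ...] = (3, 4)
    seed: int = 0

    def __post_init__(self):
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        if not set(self.nl_stages) <= {1, 2, 3, 4}:
            raise ValueError(f"nl_stages must be a subset of {{1,2,3,4}}, got {self.nl_stages}")

    @property
    def feature_dim(self) -> int:
        return 8 * self.base_width

    def groups_for(self, channels: int) -> int:
        """Group count per GN layer: gcd(gn_groups, C) so it always divides C."""
        return math.gcd(self.gn_groups, channels)

    @classmethod
    def tiny(cls, seed: int = 0) -> "EncoderConfig":
        """Small preset for CPU-scale runs: m = 128."""
        return cls(base_width=16, seed=seed)


class NonLocalBlock(nn.Module):
    """Embedded-Gaussian non-local block with channel bottleneck C/2.

    out = x + W_z · y(x), where y at each position is the softmax-normalized
    (over all positions) weighted sum of g-embeddings. With the output
    projection W_z initialized to zero the block is exactly the identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator, zero_init_out: bool = True):
        if channels % 2:
            raise ValueError(f"non-local block requires an even channel count, got {channels}")
        inner = channels // 2
        scale = 1.0 / math.sqrt(channels)
        self.theta = nn.Parameter(rng.normal(0, scale, size=(inner, channels)))
        self.phi = nn.Parameter(rng.normal(0, scale, size=(inner, channels)))
        self.g = nn.Parameter(rng.normal(0, scale, size=(inner, channels)))
        if zero_init_out:
            w_z = np.zeros((channels, inner), dtype=np.float32)
        else:
            w_z = rng.normal(0, 1.0 / math.sqrt(inner), size=(channels, inner))
        self.w_z = nn.Parameter(w_z)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)  # (N, C, P)
        theta = self.theta @ flat  # (N, C/2, P)
        phi = self.phi @ flat
        g = self.g @ flat
        attn = F.softmax(theta.swapaxes(1, 2) @ phi, axis=-1)  # (N, P, P), rows sum to 1
        y = (attn @ g.swapaxes(1, 2)).swapaxes(1, 2)  # (N, C/2, P)
        z = self.w_z @ y  # (N, C, P)
        return (flat + z).reshape(n, c, h, w)


def non_local(feature_map: np.ndarray, zero_init_out: bool = True, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialized non-local block to one C×H×W array."""
    fm = np.asarray(feature_map, dtype=np.float32)
    block = NonLocalBlock(fm.shape[0], np.random.default_rng(seed), zero_init_out=zero_init_out)
    return block(Tensor(fm[None])).numpy()[0]


class _BasicBlock(nn.Module):
    def __init__(self, cfg: EncoderConfig, in_ch: int, out_ch: int, stride: int, rng):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.gn1 = nn.GroupNorm(cfg.groups_for(out_ch), out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, padding=1)
        self.gn2 = nn.GroupNorm(cfg.groups_for(out_ch), out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride)
            self.down_gn = nn.GroupNorm(cfg.groups_for(out_ch), out_ch)
        else:
            self.down_conv = None
            self.down_gn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.gn1(self.conv1(x)).relu()
        out = self.gn2(self.conv2(out))
        identity = x if self.down_conv is None else self.down_gn(self.down_conv(x))
        return (out + identity).relu()


class Encoder(nn.Module):
    """Theta(.): frame (1,H,W) -> feature (m,), m = 8 * base_width.

    Standard ResNet-18 topology: 7x7/2 stem + 3x3/2 max-pool, four stages of
    two basic blocks at widths (w, 2w, 4w, 8w) with strides (1, 2, 2, 2),
    global average pooling. One non-local block follows the last residual
    block of each stage listed in ``config.nl_stages``.
    """

    def __init__(self, config: EncoderConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        w = config.base_width
        self.stem_conv = nn.Conv2d(config.in_channels, w, 7, rng, stride=2, padding=3)
        self.stem_gn = nn.GroupNorm(config.groups_for(w), w)
        widths = [w, 2 * w, 4 * w, 8 * w]
        strides = [1, 2, 2, 2]
        self.stages: list[nn.Module] = []
        self.nl_blocks: list[nn.Module | None] = []
        in_ch = w
        for idx, (out_ch, stride) in enumerate(zip(widths, strides), start=1):
            blocks = nn.Sequential(
                _BasicBlock(config, in_ch, out_ch, stride, rng),
                _BasicBlock(config, out_ch, out_ch, 1, rng),
            )
            self.stages.append(blocks)
            self.nl_blocks.append(
                NonLocalBlock(out_ch, rng) if idx in config.nl_stages else None
            )
            in_ch = out_ch

    @property
    def feature_dim(self) -> int:
        return self.config.feature_dim

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) -> (N, m). Requires H, W >= 32."""
        n, c, h, w = x.shape
        if h < MIN_INPUT_SIZE or w < MIN_INPUT_SIZE:
            raise ValueError(
                f"input spatial size {h}x{w} below the backbone minimum "
                f"{MIN_INPUT_SIZE}x{MIN_INPUT_SIZE}"
            )
        out = self.stem_gn(self.stem_conv(x)).relu()
        out = F.max_pool2d(out, kernel=3, stride=2, padding=1)
        for stage, nl in zip(self.stages, self.nl_blocks):
            out = stage(out)
            if nl is not None:
                out = nl(out)
        return out.mean(axis=(2, 3))  # global average pooling -> (N, m)


def encode_frames(frames: np.ndarray, encoder: Encoder) -> np.ndarray:
    """Encode a stack of frames (T, H, W) -> (T, m), deterministic given weights."""
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    return encoder(Tensor(frames[:, None])).numpy()


def encode_frame(frame: np.ndarray, encoder: Encoder, mode: str = "eval") -> np.ndarray:
    """Encode one frame (H, W) -> (m,). ``mode`` is accepted for interface
    symmetry; the map contains no stochastic layers, so train and eval agree."""
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    return encode_frames(frame, encoder)[0]
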