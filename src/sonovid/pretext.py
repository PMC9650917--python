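"""SimCLR-style contrastive pretraining of the frame encoder.

From N clips, M frames each are sampled; every frame is augmented twice by
the stochastic family tau (flip, crop-resize, zoom, brightness, contrast,
elastic deformation), embedded as f = MLP(Theta(tau(v))), L2-normalized,
and trained with the NT-Xent loss: the two views of one frame are the
positive pair, every other view in the batch is a negative. Optimization
uses LARS (layer-wise trust-ratio scaling over momentum SGD) with a
cosine-annealed learning rate; plain momentum SGD is available as a
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import resize

from . import nn
from .encoder import Encoder
from .nn import functional as F
from .nn.optim import LARS, SGD, cosine_annealing_lr
from .nn.tensor import Tensor
from .synthio import VideoSequence

__all__ = [
    "AugmentConfig",
    "PretrainConfig",
    "ProjectionHead",
    "augment",
    "sample_pretext_batch",
    "project",
    "nt_xent_loss",
    "nt_xent_loss_array",
    "pretrain",
    "linear_probe_balanced_accuracy",
]

_TRANSFORMS = ("flip", "crop", "scale", "brightness", "contrast", "elastic")


@dataclass(frozen=True)
class AugmentConfig:
    """The augmentation family tau. Crops are crop-then-resize, so shape is
    preserved; elastic strength is specified on a 64-px basis and scaled
    with image size."""

    flip_prob: float = 0.5
    crop_scale_range: tuple[float, float] = (0.6, 1.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    brightness_delta: float = 0.2
    contrast_range: tuple[float, float] = (0.8, 1.25)
    elastic_alpha: float = 20.0
    elastic_sigma: float = 4.0
    enabled: tuple[str, ...] = _TRANSFORMS

    def __post_init__(self):
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError(f"flip_prob must lie in [0,1], got {self.flip_prob}")
        for name, (lo, hi) in (("crop_scale_range", self.crop_scale_range), ("scale_range", self.scale_range), ("contrast_range", self.contrast_range)):
            if hi < lo:
                raise ValueError(f"{name} must be ordered (low <= high), got ({lo}, {hi})")
        if not 0.0 < self.crop_scale_range[0] <= self.crop_scale_range[1] <= 1.0:
            raise ValueError(f"crop_scale_range must lie within (0, 1], got {self.crop_scale_range}")
        unknown = set(self.enabled) - set(_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms enabled: {sorted(unknown)}")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(enabled=())


def _resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(img, shape, order=1, mode="reflect", anti_aliasing=False, preserve_range=True).astype(np.float32)


def augment(frame: np.ndarray, config: AugmentConfig, seed: int) -> np.ndarray:
    """Apply tau: a random combination of the enabled transforms. The output
    has the input's H×W, values clipped to [0,1]; pure in (frame, config, seed)."""
    rng = np.random.default_rng(seed)
    out = np.asarray(frame, dtype=np.float32)
    h, w = out.shape
    on = set(config.enabled)

    if "flip" in on and rng.random() < config.flip_prob:
        out = out[:, ::-1]
    if "crop" in on:
        s = rng.uniform(*config.crop_scale_range)
        ch, cw = max(1, round(h * s)), max(1, round(w * s))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        out = _resize(out[top : top + ch, left : left + cw], (h, w))
    if "scale" in on:
        z = rng.uniform(*config.scale_range)
        zh, zw = max(1, round(h * z)), max(1, round(w * z))
        zoomed = _resize(out, (zh, zw))
        if z >= 1.0:  # center crop back
            top, left = (zh - h) // 2, (zw - w) // 2
            out = zoomed[top : top + h, left : left + w]
        else:  # reflect-pad back
            py, px = h - zh, w - zw
            out = np.pad(zoomed, ((py // 2, py - py // 2), (px // 2, px - px // 2)), mode="reflect")
    if "brightness" in on:
        out = out + rng.uniform(-config.brightness_delta, config.brightness_delta)
    if "contrast" in on:
        c = rng.uniform(*config.contrast_range)
        mean = out.mean()
        out = (out - mean) * c + mean
    if "elastic" in on:
        scale = min(h, w) / 64.0
        alpha = config.elastic_alpha * scale
        sigma = config.elastic_sigma * scale
        dy = gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
        dx = gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
        yy, xx = np.mgrid[0:h, 0:w]
        out = map_coordinates(out, [yy + dy, xx + dx], order=1, mode="reflect").astype(np.float32)

    return np.clip(out, 0.0, 1.0).astype(np.float32)


def sample_pretext_batch(
    dataset: Sequence[VideoSequence],
    N: int,
    M: int,
    seed: int,
    config: AugmentConfig | None = None,
    positive_mode: str = "same_frame",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample N clips, M frames each, two augmented views per frame.

    Returns ``(views, pair_index)``: views is a (2·N·M, H, W) stack in which
    positions 2k and 2k+1 are the two views of the k-th sampled frame, and
    ``pair_index`` maps each view to its positive partner (a fixed-point-free
    involution).

    ``positive_mode='same_video'`` instead builds each positive pair from two
    *different* frames of the same clip (one augmentation each), treating the
    cross-sections of one lesion as views of one instance.
    """
    if N > len(dataset):
        raise ValueError(f"cannot sample N={N} clips from a dataset of {len(dataset)}")
    if positive_mode not in ("same_frame", "same_video"):
        raise ValueError(f"positive_mode must be 'same_frame' or 'same_video', got {positive_mode!r}")
    if config is None:
        config = AugmentConfig()
    rng = np.random.default_rng(seed)
    clip_ids = rng.choice(len(dataset), size=N, replace=False)
    views = []
    for ci in clip_ids:
        clip = dataset[int(ci)]
        t = len(clip)
        if positive_mode == "same_frame":
            frame_ids = rng.choice(t, size=M, replace=t < M)
            for fi in frame_ids:
                frame = clip.frames[int(fi)]
                for _ in range(2):
                    views.append(augment(frame, config, int(rng.integers(0, 2**31))))
        else:
            for _ in range(M):
                f1, f2 = rng.choice(t, size=2, replace=t < 2)
                for fi in (f1, f2):
                    views.append(augment(clip.frames[int(fi)], config, int(rng.integers(0, 2**31))))
    views = np.stack(views)
    k = N * M
    pair_index = np.arange(2 * k)
    pair_index[0::2] += 1
    pair_index[1::2] -= 1
    return views, pair_index


class _BatchStandardize(nn.Module):
    """1-D batch normalization (no affine) with running statistics.

    In training mode it standardizes with batch statistics and updates the
    running moments; in inference mode (and for single vectors, where batch
    moments are undefined) it uses the running moments.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if training and x.shape[0] > 1:
            centered = x - x.mean(axis=0, keepdims=True)
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean += self.momentum * (x.data.mean(axis=0) - self.running_mean)
            self.running_var += self.momentum * (var.data[0] - self.running_var)
            return centered * ((var + self.eps) ** -0.5)
        return (x - Tensor(self.running_mean)) * Tensor(
            1.0 / np.sqrt(self.running_var + self.eps)
        )


class ProjectionHead(nn.Module):
    """MLP m -> hidden -> d with batch standardization after each linear
    layer (as in reference SimCLR heads), ReLU between, L2-normalized output."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(in_dim, hidden_dim, rng)
        self.bn1 = _BatchStandardize(hidden_dim)
        self.fc2 = nn.Linear(hidden_dim, out_dim, rng)
        self.bn2 = _BatchStandardize(out_dim)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        h = self.bn1(self.fc1(x), training=training).relu()
        z = self.bn2(self.fc2(h), training=training)
        return F.l2_normalize(z, axis=-1)


def project(feature: np.ndarray, head: ProjectionHead) -> np.ndarray:
    """Map an m-feature (or a stack of them) to the unit-norm contrastive space."""
    feature = np.asarray(feature, dtype=np.float32)
    if feature.shape[-1] != head.fc1.weight.shape[1]:
        raise ValueError(
            f"feature dim {feature.shape[-1]} does not match head input {head.fc1.weight.shape[1]}"
        )
    return head(Tensor(feature)).numpy()


def nt_xent_loss(embeddings: Tensor, pair_index: np.ndarray, temperature: float) -> Tensor:
    """Normalized temperature-scaled cross-entropy over 2K unit embeddings.

    loss = mean_i -log[ exp(sim(i, p(i))/tau) / sum_{k != i} exp(sim(i, k)/tau) ]
    with cosine similarity (inner product of unit vectors).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    pair_index = np.asarray(pair_index)
    n = embeddings.shape[0]
    if np.any(pair_index == np.arange(n)) or np.any(pair_index[pair_index] != np.arange(n)):
        raise ValueError("pair_index must be a fixed-point-free involution")
    sim = (embeddings @ embeddings.swapaxes(0, 1)) * (1.0 / temperature)
    # exclude self-similarity from the softmax denominator
    mask = np.full((n, n), 0.0, dtype=np.float32)
    np.fill_diagonal(mask, -1e9)
    logp = F.log_softmax(sim + Tensor(mask), axis=-1)
    picked = logp[np.arange(n), pair_index]
    return -picked.mean()


def nt_xent_loss_array(embeddings: np.ndarray, pair_index: np.ndarray, temperature: float) -> float:
    """Convenience wrapper computing the loss on plain arrays."""
    return float(nt_xent_loss(Tensor(np.asarray(embeddings, dtype=np.float32)), pair_index, temperature).item())


@dataclass(frozen=True)
class PretrainConfig:
    """Contrastive-stage settings. The effective view batch is 2·N·M."""

    N: int = 16  # clips per batch
    M: int = 4  # frames sampled per clip
    temperature: float = 0.5
    projection_hidden: int | None = None  # None -> feature dim m
    projection_dim: int = 128
    epochs: int = 8192
    learning_rate: float = 9e-3
    weight_decay: float = 1e-6
    momentum: float = 0.9
    optimizer: str = "lars"
    positive_mode: str = "same_frame"
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.N < 1 or self.M < 1 or self.epochs < 1:
            raise ValueError("N, M and epochs must be >= 1")
        if self.optimizer not in ("lars", "sgd"):
            raise ValueError(f"optimizer must be 'lars' or 'sgd', got {self.optimizer!r}")
        if self.positive_mode not in ("same_frame", "same_video"):
            raise ValueError(f"unknown positive_mode {self.positive_mode!r}")

    @classmethod
    def tiny(cls, seed: int = 0) -> "PretrainConfig":
        """CPU-scale preset: ~7 LARS steps per epoch on a 100-clip dataset."""
        return cls(N=16, M=1, epochs=40, learning_rate=2.0, seed=seed)


def pretrain(
    dataset: Sequence[VideoSequence],
    encoder: Encoder,
    config: PretrainConfig,
    start_epoch: int = 0,
    optimizer_state: dict | None = None,
    head: ProjectionHead | None = None,
) -> tuple[ProjectionHead, list[float], dict]:
    """Contrastively pretrain ``encoder`` in place.

    Returns the projection head, the per-epoch mean loss history, and the
    optimizer state (velocity buffers) for checkpointing/resume. Aborts on
    non-finite loss."""
    if len(dataset) == 0:
        raise ValueError("pretraining dataset is empty")
    m = encoder.feature_dim
    hidden = config.projection_hidden or m
    if head is None:
        head = ProjectionHead(m, hidden, config.projection_dim, seed=config.seed + 1)
    params = encoder.parameters() + head.parameters()
    opt_cls = LARS if config.optimizer == "lars" else SGD
    opt = opt_cls(params, lr=config.learning_rate, momentum=config.momentum, weight_decay=config.weight_decay)
    if optimizer_state is not None:
        opt.load_state_dict(optimizer_state)

    n_eff = min(config.N, len(dataset))
    batches_per_epoch = max(1, len(dataset) // n_eff)
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    for epoch in range(start_epoch, start_epoch + config.epochs):
        opt.lr = cosine_annealing_lr(config.learning_rate, epoch, start_epoch + config.epochs)
        losses = []
        for _ in range(batches_per_epoch):
            views, pair_index = sample_pretext_batch(
                dataset,
                n_eff,
                config.M,
                int(rng.integers(0, 2**31)),
                config.augment,
                positive_mode=config.positive_mode,
            )
            z = head(encoder(Tensor(views[:, None])), training=True)
            loss = nt_xent_loss(z, pair_index, config.temperature)
            value = loss.item()
            if not np.isfinite(value):
                raise FloatingPointError(f"contrastive loss diverged (non-finite) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
        history.append(float(np.mean(losses)))
    return head, history, opt.state_dict()


def linear_probe_balanced_accuracy(
    encoder: Encoder,
    train_clips: Sequence[VideoSequence],
    test_clips: Sequence[VideoSequence],
) -> float:
    """Balanced accuracy of a logistic-regression probe on frozen encoder
    features (per-clip mean over frame features) — the standard linear
    evaluation protocol for self-supervised representations."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import balanced_accuracy_score

    from .encoder import encode_frames
    from .synthio import MALIGNANT

    def featurize(clips):
        x = np.stack([encode_frames(c.frames, encoder).mean(axis=0) for c in clips])
        y = np.array([1 if c.label == MALIGNANT else 0 for c in clips])
        return x, y

    x_tr, y_tr = featurize(train_clips)
    x_te, y_te = featurize(test_clips)
    clf = LogisticRegression(max_iter=3000).fit(x_tr, y_tr)
    return float(balanced_accuracy_score(y_te, clf.predict(x_te)))
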