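"""Supervised video-level training, prediction and evaluation.

A clip's sampled frames pass through the frame encoder; multi-meta attention
aggregates the T frame features into one m-vector; a single linear layer
m -> 2 produces benign/malignant logits trained with cross-entropy under
momentum SGD (optionally warm-started from a contrastive checkpoint).

Evaluation reports the six standard metrics — accuracy, average precision,
sensitivity, specificity, F1 and AUC — with malignant as the positive class,
plus the ROC curve. AUC uses the Mann–Whitney rank formulation (ties count
1/2); AP is the step-interpolated area under the precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import nn
from .aggregator import AttentionConfig, MultiMetaAttention
from .encoder import Encoder
from .nn import functional as F
from .nn.optim import SGD
from .nn.tensor import Tensor
from .synthio import BENIGN, MALIGNANT, DatasetIndex, VideoSequence

__all__ = [
    "TrainConfig",
    "Prediction",
    "Metrics",
    "VideoClassifier",
    "sample_frames",
    "train_classifier",
    "predict",
    "compute_metrics",
    "roc_curve",
]

LABEL_TO_INT = {BENIGN: 0, MALIGNANT: 1}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}


@dataclass(frozen=True)
class TrainConfig:
    """Supervised-stage settings (defaults follow the reference protocol)."""

    epochs: int = 320
    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 5e-4
    sample_length: int = 16
    batch_size: int = 8
    frame_sampling: str = "evenly_spaced"
    class_weighting: bool = False
    eval_interval: int = 0  # 0: evaluate only after the final epoch
    seed: int = 0

    def __post_init__(self):
        if self.sample_length < 1:
            raise ValueError("sample_length must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")
        if self.frame_sampling not in ("evenly_spaced", "random_jitter"):
            raise ValueError(f"unknown frame_sampling mode {self.frame_sampling!r}")

    @classmethod
    def tiny(cls, seed: int = 0) -> "TrainConfig":
        """CPU-scale preset: short schedule, higher LR, T=8."""
        return cls(epochs=20, learning_rate=0.02, sample_length=8, seed=seed)


@dataclass(frozen=True)
class Prediction:
    label: str
    malignant_score: float


def sample_frames(sequence: VideoSequence, T: int, mode: str = "evenly_spaced", seed: int = 0) -> VideoSequence:
    """Subsample a clip to exactly T frames.

    ``evenly_spaced``: indices round(k (len-1)/(T-1)); short clips repeat
    frames (sampling with replacement). ``random_jitter``: one uniform draw
    per evenly spaced bin.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    n = len(sequence)
    if mode == "evenly_spaced":
        if T == 1:
            idx = np.array([0])
        else:
            idx = np.round(np.arange(T) * (n - 1) / (T - 1)).astype(int)
    elif mode == "random_jitter":
        rng = np.random.default_rng(seed)
        edges = np.floor(np.arange(T + 1) * n / T).astype(int)
        idx = np.array([int(rng.integers(lo, max(lo + 1, hi))) for lo, hi in zip(edges[:-1], edges[1:])])
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return VideoSequence(id=sequence.id, frames=sequence.frames[idx], label=sequence.label)


class VideoClassifier(nn.Module):
    """Encoder + multi-meta attention + linear head (m -> 2)."""

    def __init__(self, encoder: Encoder, attention: MultiMetaAttention | None = None, seed: int = 0):
        m = encoder.feature_dim
        self.encoder = encoder
        self.attention = attention or MultiMetaAttention(AttentionConfig(feature_dim=m, seed=seed + 7))
        self.head = nn.Linear(m, 2, np.random.default_rng(seed + 11))

    def forward(self, frames: Tensor, n_clips: int, t: int) -> Tensor:
        """frames: (n_clips*t, 1, H, W) -> logits (n_clips, 2)."""
        feats = self.encoder(frames).reshape(n_clips, t, self.encoder.feature_dim)
        video_feat = self.attention(feats)
        return self.head(video_feat)


def predict(model: VideoClassifier, sequence: VideoSequence) -> Prediction:
    """Classify one clip using all of its frames (any length; the attention
    aggregation is length-agnostic and order-invariant)."""
    frames = sequence.frames[:, None]
    logits = model(Tensor(frames), 1, len(sequence)).numpy()[0]
    shifted = logits - logits.max()
    probs = np.exp(shifted) / np.exp(shifted).sum()
    score = float(probs[LABEL_TO_INT[MALIGNANT]])
    return Prediction(label=MALIGNANT if score >= 0.5 else BENIGN, malignant_score=score)


def _score_split(model: VideoClassifier, clips: Sequence[VideoSequence]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([predict(model, c).malignant_score for c in clips])
    labels = np.array([LABEL_TO_INT[c.label] for c in clips])
    return scores, labels


def train_classifier(
    dataset: Sequence[VideoSequence],
    index: DatasetIndex,
    encoder: Encoder,
    config: TrainConfig,
) -> tuple[VideoClassifier, list[dict]]:
    """Train the full video classifier on the 'train' split of ``index``.

    Returns the trained model and a per-epoch history of train loss (plus
    test metrics every ``eval_interval`` epochs and after the final epoch).
    """
    by_id = {c.id: c for c in dataset}
    train_clips = [by_id[i] for i in index.ids("train")]
    test_clips = [by_id[i] for i in index.ids("test")]
    train_labels = {LABEL_TO_INT[c.label] for c in train_clips}
    if not train_clips:
        raise ValueError("training split is empty")
    if len(train_labels) < 2:
        raise ValueError("training split must contain both classes")

    model = VideoClassifier(encoder, seed=config.seed)
    opt = SGD(model.parameters(), lr=config.learning_rate, momentum=config.momentum, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    t = config.sample_length

    class_weights = None
    if config.class_weighting:
        counts = np.bincount([LABEL_TO_INT[c.label] for c in train_clips], minlength=2)
        class_weights = counts.sum() / (2.0 * np.maximum(counts, 1))

    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_clips))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_clips[i] for i in order[start : start + config.batch_size]]
            stacks = []
            for clip in batch:
                sub = sample_frames(clip, t, config.frame_sampling, seed=int(rng.integers(0, 2**31)))
                stacks.append(sub.frames)
            frames = np.concatenate(stacks)[:, None]
            labels = np.array([LABEL_TO_INT[c.label] for c in batch])
            logits = model(Tensor(frames), len(batch), t)
            if class_weights is None:
                loss = F.cross_entropy(logits, labels)
            else:
                logp = F.log_softmax(logits, axis=-1)
                picked = logp[np.arange(len(batch)), labels]
                wts = class_weights[labels]
                loss = -(picked * Tensor(wts)).sum() * (1.0 / float(wts.sum()))
            value = loss.item()
            if not np.isfinite(value):
                raise FloatingPointError(f"training loss diverged (non-finite) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
        entry: dict = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        is_last = epoch == config.epochs - 1
        if test_clips and (is_last or (config.eval_interval and (epoch + 1) % config.eval_interval == 0)):
            scores, labels = _score_split(model, test_clips)
            entry["test_metrics"] = compute_metrics(scores, labels).as_dict()
        history.append(entry)
    return model, history


# ------------------------------------------------------------------- metrics


@dataclass(frozen=True)
class Metrics:
    """The six evaluation metrics plus confusion counts at the threshold.

    Malignant is the positive class. When only one class is present, AUC and
    AP are undefined: they are reported as NaN with their flags set False.
    """

    accuracy: float
    average_precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    tp: int
    fn: int
    tn: int
    fp: int
    threshold: float = 0.5
    auc_defined: bool = True
    ap_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "average_precision": self.average_precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "threshold": self.threshold,
            "auc_defined": self.auc_defined,
            "ap_defined": self.ap_defined,
        }


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = (R_+ - n_+(n_+ + 1)/2) / (n_+ n_-); ties contribute 1/2."""
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _step_average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP = sum over descending score thresholds of (delta recall) * precision."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = int(y.sum())
    boundaries = np.flatnonzero(np.diff(s)) + 1  # group tied scores
    cut = np.concatenate([boundaries, [len(s)]])
    tp_cum = np.cumsum(y)[cut - 1]
    precision = tp_cum / cut
    recall = tp_cum / n_pos
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev) * precision).sum())


def compute_metrics(scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5) -> Metrics:
    """Six-metric report from malignant-probability scores and 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels) or len(scores) < 1:
        raise ValueError("scores and labels must have equal, nonzero length")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    accuracy = (tp + tn) / len(labels)
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * precision * sensitivity / (precision + sensitivity) if n_pos and (precision + sensitivity) else 0.0
    both = bool(n_pos and n_neg)
    auc = _mann_whitney_auc(scores, labels) if both else float("nan")
    ap = _step_average_precision(scores, labels) if both else float("nan")
    return Metrics(
        accuracy=float(accuracy),
        average_precision=ap,
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        f1=float(f1),
        auc=auc,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        threshold=threshold,
        auc_defined=both,
        ap_defined=both,
    )


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """Ordered (FPR, TPR) points from (0,0) to (1,1); tied scores are grouped
    so the trapezoidal area equals the Mann–Whitney AUC exactly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if not (n_pos and n_neg):
        raise ValueError("ROC requires both classes to be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    boundaries = np.flatnonzero(np.diff(s)) + 1
    cut = np.concatenate([boundaries, [len(s)]])
    tp_cum = np.cumsum(y)[cut - 1]
    fp_cum = cut - tp_cum
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    return np.column_stack([fpr, tpr])
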