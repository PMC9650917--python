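"""Run configuration: presets, YAML files with flat dotted keys, overrides.

Two presets ship:

* ``paper_default`` — the reference protocol: supervised SGD for 320 epochs,
  lr 1e-4, momentum 0.9, weight decay 5e-4, sample length T=16, batch 8;
  contrastive stage with LARS for 8192 epochs, lr 9e-3, weight decay 1e-6,
  a 64-frame (128-view) batch, NT-Xent, cosine annealing; full-width
  encoder (m=512).
* ``tiny`` — a CPU-scale preset (m=128, T=8, short schedules) used by the
  test-suite and the worked examples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace
from pathlib import Path
from typing import Any

import yaml

from .aggregator import AttentionConfig
from .encoder import EncoderConfig
from .pretext import AugmentConfig, PretrainConfig
from .trainer import TrainConfig

__all__ = ["RunConfig", "build_preset", "load_yaml_overrides", "apply_overrides"]

PRESETS = ("paper_default", "tiny")


@dataclasses.dataclass
class RunConfig:
    preset: str
    encoder: EncoderConfig
    pretrain: PretrainConfig
    train: TrainConfig
    attention: AttentionConfig
    seed: int = 0
    device: str = "cpu"

    def to_flat_dict(self) -> dict[str, Any]:
        flat: dict[str, Any] = {"preset": self.preset, "seed": self.seed, "device": self.device}
        for group in ("encoder", "pretrain", "train", "attention"):
            cfg = getattr(self, group)
            for k, v in dataclasses.asdict(cfg).items():
                flat[f"{group}.{k}"] = list(v) if isinstance(v, tuple) else v
        return flat


def build_preset(preset: str, seed: int = 0) -> RunConfig:
    if preset == "paper_default":
        encoder = EncoderConfig(seed=seed)
        pretrain_cfg = PretrainConfig(N=16, M=4, seed=seed)  # 64 frames -> 128 views per batch
        train_cfg = TrainConfig(seed=seed)
    elif preset == "tiny":
        encoder = EncoderConfig.tiny(seed=seed)
        pretrain_cfg = PretrainConfig.tiny(seed=seed)
        train_cfg = TrainConfig.tiny(seed=seed)
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    attention = AttentionConfig(feature_dim=encoder.feature_dim, seed=seed)
    return RunConfig(preset=preset, encoder=encoder, pretrain=pretrain_cfg, train=train_cfg, attention=attention, seed=seed)


def load_yaml_overrides(path: str | Path) -> dict[str, Any]:
    """Read a YAML mapping of flat dotted keys (e.g. ``train.epochs: 20``)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping of dotted keys")
    return data


def apply_overrides(config: RunConfig, overrides: dict[str, Any]) -> RunConfig:
    """Apply ``group.field`` overrides onto a preset; unknown keys raise."""
    grouped: dict[str, dict[str, Any]] = {}
    for key, value in overrides.items():
        if key in ("seed", "device", "preset"):
            config = replace(config, **{key: value})
            continue
        if "." not in key:
            raise KeyError(f"override key {key!r} must be 'group.field'")
        group, fname = key.split(".", 1)
        if group not in ("encoder", "pretrain", "train", "attention"):
            raise KeyError(f"unknown config group {group!r}")
        grouped.setdefault(group, {})[fname] = value
    for group, fields in grouped.items():
        cfg = getattr(config, group)
        valid = {f.name for f in dataclasses.fields(cfg)}
        unknown = set(fields) - valid
        if unknown:
            raise KeyError(f"unknown fields for {group}: {sorted(unknown)}")
        coerced = {}
        for k, v in fields.items():
            if isinstance(v, list):
                v = tuple(v)
            if group == "pretrain" and k == "augment" and isinstance(v, dict):
                v = AugmentConfig(**{ak: tuple(av) if isinstance(av, list) else av for ak, av in v.items()})
            coerced[k] = v
        config = replace(config, **{group: replace(cfg, **coerced)})
    return config


def write_snapshot(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration next to a run's outputs."""
    flat = config.to_flat_dict()
    flat["pretrain.augment"] = {
        k: list(v) if isinstance(v, tuple) else v
        for k, v in dataclasses.asdict(config.pretrain.augment).items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)
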