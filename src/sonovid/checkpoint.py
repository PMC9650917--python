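"""Checkpoint archive: a single ``.npz`` holding a format version, the
configs (as JSON), and every parameter array. Loading verifies that the
embedded encoder config matches the requested one."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np

from .encoder import Encoder, EncoderConfig

FORMAT_VERSION = 1


def _config_to_json(config: Any) -> str:
    return json.dumps(dataclasses.asdict(config), sort_keys=True)


def save_checkpoint(
    path: str | Path,
    encoder: Encoder,
    extra_modules: dict[str, Any] | None = None,
    meta: dict | None = None,
    optimizer_state: dict | None = None,
) -> None:
    arrays: dict[str, np.ndarray] = {}
    for name, p in encoder.named_parameters():
        arrays[f"encoder/{name}"] = p.data
    for mod_name, module in (extra_modules or {}).items():
        for name, p in module.named_parameters():
            arrays[f"{mod_name}/{name}"] = p.data
    if optimizer_state is not None:
        for i, v in enumerate(optimizer_state.get("velocity", [])):
            arrays[f"optim/velocity/{i}"] = v
    payload = {
        "version": FORMAT_VERSION,
        "encoder_config": dataclasses.asdict(encoder.config),
        "meta": meta or {},
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(payload, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[Encoder, dict[str, dict[str, np.ndarray]], dict]:
    """Rebuild the encoder and return (encoder, grouped extra arrays, meta)."""
    with np.load(path) as data:
        payload = json.loads(bytes(data["__meta__"]).decode())
        if payload["version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {payload['version']}")
        cfg_dict = payload["encoder_config"]
        cfg_dict["nl_stages"] = tuple(cfg_dict["nl_stages"])
        config = EncoderConfig(**cfg_dict)
        encoder = Encoder(config)
        enc_state = {}
        groups: dict[str, dict[str, np.ndarray]] = {}
        for key in data.files:
            if key == "__meta__":
                continue
            prefix, name = key.split("/", 1)
            if prefix == "encoder":
                enc_state[name] = data[key]
            else:
                groups.setdefault(prefix, {})[name] = data[key]
        encoder.load_state_dict(enc_state)
    return encoder, groups, payload["meta"]
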