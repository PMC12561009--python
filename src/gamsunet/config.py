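"""Run configuration: packaged defaults, YAML overrides, echo-to-disk."""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

from .network import NetworkConfig
from .phantom import PhantomConfig
from .train_infer import TrainConfig


def default_config() -> dict:
    """The frozen packaged defaults (deep copy, safe to mutate)."""
    text = resources.files("gamsunet.configs").joinpath("default.yaml").read_text()
    return yaml.safe_load(text)


def _deep_update(base: dict, override: dict) -> dict:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """defaults <- YAML file <- explicit overrides, in that order."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, copy.deepcopy(overrides))
    return cfg


def network_config(cfg: dict) -> NetworkConfig:
    d = dict(cfg["network"])
    d["widths"] = tuple(d["widths"])
    return NetworkConfig(**d)


def train_config(cfg: dict) -> TrainConfig:
    return TrainConfig(seed=cfg.get("seed", 0), **cfg["train"])


def phantom_config(cfg: dict) -> PhantomConfig:
    d = dict(cfg["phantom"])
    d["dims"] = tuple(d["dims"])
    d["spacing_range"] = tuple(d["spacing_range"])
    return PhantomConfig(**d)


def echo_config(cfg: dict, out_dir: str | Path, name: str = "resolved_config.yaml") -> Path:
    """Write the fully resolved configuration into the run directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
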