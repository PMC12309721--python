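"""Run configuration: documented defaults, YAML overrides, provenance.

Defaults are the published operating point of the method: Adam learning rate
3e-5, weight decay 1e-5, input dropout 0.4, batch size 64, 25-batch loss
window with 200-batch patience, simulated cell numbers 200-4000, minimum 5
cells per class, CPM >= 1 in more than 50% of samples, KS threshold 0.4, and
missing-gene guards at 1% (warn) / 20% (refuse).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .model import ModelConfig
from .simulate import SimulationConfig

DEFAULTS: dict = {
    "seed": 0,
    "model": {
        "hidden_sizes": [32, 16],
        "input_dropout": 0.4,
        "learning_rate": 3e-5,
        "weight_decay": 1e-5,
        "batch_size": 64,
        "window": 25,
        "patience": 200,
        "max_batches": None,
    },
    "simulation": {
        "purity_min": 0.0,
        "purity_max": 1.0,
        "cells_min": 200,
        "cells_max": 4000,
        "min_cells_per_class": 5,
        "batch_size": 64,
    },
    "features": {
        "cpm_threshold": 1.0,
        "prevalence_fraction": 0.5,
        "ks_threshold": 0.4,
    },
    "predict": {
        "warn_missing": 0.01,
        "max_missing": 0.20,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_run_config(yaml_path: str | Path | None = None, **overrides) -> dict:
    """Defaults <- YAML file <- keyword overrides, merged recursively."""
    cfg = DEFAULTS
    if yaml_path is not None:
        with open(yaml_path) as fh:
            from_file = yaml.safe_load(fh) or {}
        if not isinstance(from_file, dict):
            raise ValueError(f"{yaml_path}: config must be a YAML mapping")
        cfg = _deep_merge(cfg, from_file)
    return _deep_merge(cfg, overrides)


def model_config_from(cfg: dict, seed: int | None = None) -> ModelConfig:
    return ModelConfig(**cfg["model"], seed=cfg["seed"] if seed is None else seed)


def simulation_config_from(cfg: dict, seed: int | None = None) -> SimulationConfig:
    return SimulationConfig(**cfg["simulation"], seed=cfg["seed"] if seed is None else seed)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_provenance(out_dir: str | Path, command: str, cfg: dict, seed: int) -> Path:
    """Record versions, seed and config hash next to a command's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{command}.provenance.json"
    with open(path, "w") as fh:
        json.dump(
            {
                "command": command,
                "package_version": __version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "platform": platform.platform(),
                "seed": seed,
                "config_hash": config_hash(cfg),
                "config": cfg,
            },
            fh,
            indent=1,
            default=str,
        )
    return path


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("puritynet")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())
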