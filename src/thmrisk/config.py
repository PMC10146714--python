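"""Configuration loading and merging.

The package ships a complete default configuration (``data/defaults.yaml``)
covering the exposure-factor parameter table, the per-species constants, and
the synthetic water generator.  User YAML files are deep-merged over the
defaults, so a run config only needs to state what it changes, e.g.::

    parameters:
      t: {lower: 5, mode: 8, upper: 12}
    water:
      species:
        tcm: {target_mean: 6.0}
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["default_config", "load_config", "merge_config", "config_hash"]


def default_config() -> dict[str, Any]:
    """Return a deep copy of the shipped default configuration."""
    text = resources.files("thmrisk.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    """Recursively merge ``override`` into ``base`` (without mutating either)."""
    merged = copy.deepcopy(dict(base))
    for key, value in override.items():
        if (
            key in merged
            and isinstance(merged[key], Mapping)
            and isinstance(value, Mapping)
        ):
            merged[key] = merge_config(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load the defaults, optionally overlaid with a user YAML file."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text())
        if user:
            cfg = merge_config(cfg, user)
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration, for run manifests."""
    canonical = json.dumps(cfg, sort_keys=True, default=float)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
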