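"""YAML run configuration for the analysis drivers.

A run config is a small YAML mapping with optional sections; anything
absent falls back to the package defaults, so `{}` is a valid config.

    seed: 42
    atmosphere:
      path: null          # CSV with year,delta14c_permil; null -> synthetic curve
      lag_years: 0
      offset_permil: 0.0
    synthetic:            # forwarded to SyntheticConfig
      sd_co2_permil: 2.0
      sd_soc_permil: 7.0
    fit:
      n_iter: 10000
      n_sub: 200
    aggregate:
      tt_weight: flux     # or 'decomposability'
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml

from .synthetic import SyntheticConfig

__all__ = ["DEFAULT_RUN_CONFIG", "load_run_config", "synthetic_config_from"]

DEFAULT_RUN_CONFIG: Dict[str, Any] = {
    "seed": 0,
    "atmosphere": {"path": None, "lag_years": 0, "offset_permil": 0.0},
    "synthetic": {},
    "fit": {"n_iter": 10_000, "n_sub": 200},
    "aggregate": {"tt_weight": "flux"},
}


def _merge(base: Dict[str, Any], override: Dict[str, Any]) -> Dict[str, Any]:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_run_config(path: Optional[Union[str, Path]] = None) -> Dict[str, Any]:
    """Read a YAML run config and merge it over the defaults."""
    if path is None:
        return dict(DEFAULT_RUN_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("run config must be a YAML mapping")
    return _merge(DEFAULT_RUN_CONFIG, user)


def synthetic_config_from(cfg: Dict[str, Any]) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from the ``synthetic`` section."""
    section = dict(cfg.get("synthetic", {}))
    if "carbonate_fractions" in section:
        section["carbonate_fractions"] = tuple(section["carbonate_fractions"])
    valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
    if "seed" not in section:
        section["seed"] = cfg.get("seed", 0)
    return SyntheticConfig(**section)
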