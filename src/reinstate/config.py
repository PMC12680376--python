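"""YAML pipeline configuration with defaults, merging, and validation."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from reinstate.errors import ConfigurationError
from reinstate.sim.catalog import DEFAULT_CATEGORIES

DEFAULTS = {
    "seed": 0,
    "catalog": {
        "n_themes": 60,
        "exemplars_per_theme": 4,
        "categories": list(DEFAULT_CATEGORIES),
    },
    "design": {
        "n_children": 20,
        "n_adults": 20,
        "runs_per_session": 3,
        "recent_per_run": 10,
        "remote_per_run": 10,
    },
    "learning": {
        "accuracy": {"children": 0.75, "adults": 0.92},
        "criterion": 0.83,
        "min_cycles": 2,
        "max_cycles": 4,
    },
    "behavior": {
        "retention_means": {
            "children": {"recent": 82.0, "remote_short": 78.0, "remote_long": 55.0},
            "adults": {"recent": 95.0, "remote_short": 93.0, "remote_long": 80.0},
        },
        "retention_sd": 8.0,
        "timeout_prob": {"children": 0.054, "adults": 0.0},
    },
    "patterns": {
        "n_voxels": 200,
        "sigma": 1.0,
        "a": 1.0,
        "b": 0.0,
        "rois": ["HCa", "HCp", "PHGa", "mPFC", "vlPFC"],
        "control_rois": ["WM"],
        "rho": {
            "children": {"recent": 0.08, "remote_short": 0.05, "remote_long": 0.02},
            "adults": {"recent": 0.10, "remote_short": 0.06, "remote_long": 0.02},
        },
        "gamma": {
            "children": {"recent": 0.0, "remote_short": 0.0, "remote_long": 0.08},
            "adults": {"recent": 0.0, "remote_short": 0.0, "remote_long": 0.0},
        },
        "gamma_incorrect": 0.0,
    },
    "stats": {
        "n_perm": 1999,
        "alpha": 0.05,
    },
    "plsc": {
        "n_perm": 1000,
        "n_boot": 1000,
        "z_threshold": 1.96,
        "metric": "scene_reinstatement",
        "condition": "remote_long",
    },
}


def _merge(base, override, path=""):
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(f"unknown config field: {where}")
        if isinstance(base[key], dict) and not _is_leaf_dict(where):
            if not isinstance(value, dict):
                raise ConfigurationError(f"{where}: expected a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _is_leaf_dict(path: str) -> bool:
    # mappings whose keys are data (groups, delays), not schema fields
    leaves = (
        "learning.accuracy",
        "behavior.retention_means",
        "behavior.timeout_prob",
        "patterns.rho",
        "patterns.gamma",
    )
    return path in leaves


def load_config(path=None, overrides=None) -> dict:
    """Load config from YAML, merged over defaults; validates field names."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config root must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_default_config() -> str:
    return yaml.safe_dump(DEFAULTS, sort_keys=False)
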