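"""YAML pipeline configuration with strict (unknown-key rejecting) loading.

Every tunable default of the pipeline lives in :data:`DEFAULTS`; YAML files
override keys selectively and any unrecognized key is rejected by name.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .core import Morphology

__all__ = ["DEFAULTS", "load_config", "merge_config", "config_hash", "PipelineConfig"]

DEFAULTS: dict = {
    "seed": 0,
    "log_level": "INFO",
    "synth": {
        "fs": 500.0,
        "n_beats": 300,
        "mean_rr": 900.0,
        "lf_amp": 25.0,
        "lf_freq": 0.1,
        "hf_amp": 15.0,
        "hf_freq": 0.3,
        "rr_noise_sd": 10.0,
        "qt_alpha": 400.0,
        "qt_beta": 0.5,
        "t_morphology": "monophasic_pos",
        "t_amp_frac": 0.35,
        "r_amp": 1.0,
        "noise_sd": 0.0,
        "baseline_wander_amp": 0.0,
        "baseline_wander_freq": 0.25,
    },
    "delineator": {
        "band_lo": 0.5,
        "band_hi": 40.0,
        "q_window": 150.0,
        "t_window_lo": 200.0,
        "t_window_hi": 500.0,
        "t_window_rr_frac": 0.7,
        "t_offset_method": "auto",
        "flat_frac": 0.10,
        "notch_min_sep": 40.0,
        "peaked_frac": 0.60,
        "offset_return_frac": 0.10,
        "refractory_ms": 200.0,
        "searchback_frac": 0.5,
        "slope_frac": 0.02,
        "smooth_ms": 12.0,
    },
    "intervals": {
        "correction_method": "bazett",
        "exclude_artifacts": False,
    },
    "hrv": {
        "lf_band": [0.04, 0.15],
        "hf_band": [0.15, 0.40],
        "mse_scales": [1, 2, 3, 4, 5],
        "sampen_m": 2,
        "sampen_r_frac": 0.2,
        "bei_implementation": "lf_band_sampen",
    },
    "evaluation": {
        "match_tol_ms": 150.0,
        "quality_frac": 0.15,
    },
}


class ConfigError(ValueError):
    pass


def merge_config(base: dict, override: dict, path: str = "") -> dict:
    """Recursive merge rejecting keys absent from the defaults tree."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = merge_config(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load defaults, then a YAML file, then programmatic overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        cfg = merge_config(cfg, data)
    if overrides:
        cfg = merge_config(cfg, overrides)
    Morphology(cfg["synth"]["t_morphology"])  # validates the label
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


# Convenience alias: the validated nested dict IS the pipeline configuration.
PipelineConfig = dict
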