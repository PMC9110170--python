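"""YAML run configuration with strict key validation."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS = {
    "audio": {
        "frame_ms": 25.0,
        "hop_ms": 10.0,
        "n_fft": 512,
        "n_mel": 26,
        "pitch_band": [50.0, 500.0],
        "preemphasis": 0.97,
        "noise_window": 11,
        "denoise": True,
    },
    "stats": {
        "set": ["mean", "std", "skewness", "kurtosis"],
    },
    "fusion": {
        "similarity": "cosine",
        "temperature": 1.0,
        "weight_override": None,
    },
    "svm": {
        "C": 1.0,
        "sigma_rule": "scale",
        "degree": 3,
    },
    "eval": {
        "k": 5,
        "seed": 42,
        "condition": "(F+V+G)att",
    },
    "simulate": {
        "n_subjects": 40,
        "prevalence": 0.5,
        "effect": 0.0,
        "seed": 0,
        "fps": 25.0,
        "sample_rate": 16000,
        "face_duration": 30.0,
        "gait_duration": 8.0,
        "voice_segments": 3,
        "voice_duration": 1.0,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key {here!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Defaults merged with an optional YAML file; unknown keys rejected."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: top-level config must be a mapping")
    return _merge(DEFAULTS, user)


def dump_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
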