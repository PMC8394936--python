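"""Structured configuration: one YAML file with sections, validated on load.

Sections mirror the pipeline stages; every key has a default, so an empty
or absent file yields the standard configuration (0.15 filter / 0.75
confidence thresholds, the default anchor layout, the default synthetic
noise model).  Unknown sections or keys are rejected to catch typos.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .detection import DetectionConfig
from .synth import DEFAULT_NOISE_PARAMS

DEFAULTS = {
    "detection": {
        "anchor_scales": [96, 128, 160],
        "anchor_stride": 16,
        "filter_threshold": 0.15,
        "confident_threshold": 0.75,
        "nms_iou": 0.5,
        "proximity_radius": 85.0,
    },
    "angles": {
        "corr_threshold_sd": 2.0,
        "min_component_px": 25,
        "pair_radius_frac": 0.35,
    },
    "simulate": {
        "n_cilia": 12,
        "class_mix": [0.7, 0.15, 0.15],
        "image_size": [814, 814],
        "noise": dict(DEFAULT_NOISE_PARAMS),
    },
    "evaluate": {
        "match_radius": 55.0,
    },
}

__all__ = ["DEFAULTS", "load_config", "detection_config_from"]


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in base:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config section {path + key!r} must be a mapping")
            out[key] = _merge(base[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config over the defaults; None means pure defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _merge(DEFAULTS, data)


def detection_config_from(cfg: dict) -> DetectionConfig:
    d = cfg["detection"]
    return DetectionConfig(
        anchor_scales=tuple(d["anchor_scales"]),
        anchor_stride=int(d["anchor_stride"]),
        filter_threshold=float(d["filter_threshold"]),
        confident_threshold=float(d["confident_threshold"]),
        nms_iou=float(d["nms_iou"]),
        proximity_radius=float(d["proximity_radius"]),
    )
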