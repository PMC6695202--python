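"""Structured configuration: one YAML/JSON file for a whole experiment.

Sections mirror the package's parameter dataclasses (morphology, membrane,
calcium, background, te, scan); unknown keys are rejected so typos fail
loudly.  ``default_config`` writes every default value, which doubles as a
readable inventory of the model's parameters.
"""

from __future__ import annotations

from dataclasses import asdict, fields
import json

import yaml

from .biophysics import CalciumParams, MembraneParams
from .infotheory import TEConfig
from .morphology import MorphologyConfig
from .synapses import BackgroundConfig

__all__ = ["default_config", "load_config", "save_config", "build_params"]

_SECTIONS = {
    "morphology": MorphologyConfig,
    "membrane": MembraneParams,
    "calcium": CalciumParams,
    "background": BackgroundConfig,
    "te": TEConfig,
}

_SCAN_DEFAULTS = {
    "gains": [0.0, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 2.4, 4.8, 7.2, 9.6],
    "seeds": [0, 1, 2, 3, 4, 5],
    "duration_s": 125.0,
    "dt_ms": 0.05,
    "target_rate_hz": 4.0,
    "rate_tolerance_hz": 0.3,
}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def default_config() -> dict:
    cfg = {name: _jsonable(asdict(cls())) for name, cls in _SECTIONS.items()}
    cfg["scan"] = dict(_SCAN_DEFAULTS)
    return cfg


def build_params(cfg: dict) -> dict:
    """Instantiate the parameter objects named in a config mapping."""
    out: dict = {}
    for name, cls in _SECTIONS.items():
        section = dict(cfg.get(name, {}))
        known = {f.name for f in fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
        if name == "morphology" and section.get("level_lengths") is not None:
            section["level_lengths"] = tuple(section["level_lengths"])
        if name == "morphology" and section.get("level_diameters") is not None:
            section["level_diameters"] = tuple(section["level_diameters"])
        out[name] = cls(**section)
    out["scan"] = {**_SCAN_DEFAULTS, **cfg.get("scan", {})}
    return out


def load_config(path: str) -> dict:
    with open(path) as fh:
        if path.endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def save_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(cfg, fh, indent=2)
        else:
            yaml.safe_dump(cfg, fh, sort_keys=False)
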