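"""YAML run configuration: validation, merging, and typed sub-configs.

A run config is a flat mapping whose keys must belong to the pen-simulator
or tracker parameter sets (plus a few run-level options); unknown keys are
rejected outright so typos never silently fall back to defaults.
Precedence when building a run: CLI flag > config file > built-in preset.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .simulate import PenConfig
from .tracker import TrackerConfig

__all__ = ["load_config", "split_config", "make_tracker_config", "make_pen_config"]

_PEN_KEYS = {f.name for f in dataclasses.fields(PenConfig)}
_TRACKER_KEYS = {f.name for f in dataclasses.fields(TrackerConfig)}
_RUN_KEYS = {"iou_thr", "seed", "mode", "preset", "verbosity"}
_ALL_KEYS = _PEN_KEYS | _TRACKER_KEYS | _RUN_KEYS


def load_config(path: str | Path | None) -> dict:
    """Load and validate a YAML config file; None gives an empty config."""
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    unknown = sorted(set(raw) - _ALL_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    return raw


def split_config(cfg: dict) -> tuple[dict, dict, dict]:
    """Split a flat validated config into (pen, tracker, run) sub-dicts."""
    pen = {k: v for k, v in cfg.items() if k in _PEN_KEYS}
    trk = {k: v for k, v in cfg.items() if k in _TRACKER_KEYS}
    run = {k: v for k, v in cfg.items() if k in _RUN_KEYS}
    return pen, trk, run


def make_tracker_config(cfg: dict, mode: str = "improved") -> TrackerConfig:
    """Tracker config from a flat mapping; mode selects improved/baseline."""
    _, trk, _ = split_config(cfg)
    if mode == "baseline":
        return TrackerConfig.baseline(**trk)
    if mode == "improved":
        return TrackerConfig(**trk)
    raise ValueError(f"unknown mode {mode!r}; expected 'improved' or 'baseline'")


def make_pen_config(cfg: dict, **overrides) -> PenConfig:
    pen, _, _ = split_config(cfg)
    pen.update(overrides)
    for key in ("behavior_transition", "class_confusion"):
        if key in pen:
            pen[key] = np.asarray(pen[key], dtype=float)
    return PenConfig(**pen)
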