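"""Default configuration: parameters and scenario geometry as data.

All tunable defaults (model parameters, grid, run control, scenario
geometry) live in ``defaults.yaml`` next to this module; code reads them
from there so that recalibration never requires touching logic.
"""

from __future__ import annotations

import copy
from importlib import resources

import numpy as np
import yaml

from .core import DiskGrid, ModelParams

__all__ = ["load_defaults", "default_params", "default_grid", "merge_config"]

_cache: dict | None = None


def load_defaults() -> dict:
    """The parsed contents of the packaged ``defaults.yaml`` (a copy)."""
    global _cache
    if _cache is None:
        text = resources.files("gastruflow").joinpath("defaults.yaml").read_text()
        _cache = yaml.safe_load(text)
    return copy.deepcopy(_cache)


def default_params(**overrides) -> ModelParams:
    cfg = load_defaults()["params"]
    cfg.update(overrides)
    return ModelParams(**cfg)


def default_grid(nr: int | None = None, ntheta: int | None = None) -> DiskGrid:
    cfg = load_defaults()["grid"]
    return DiskGrid(
        nr=nr if nr is not None else cfg["nr"],
        ntheta=ntheta if ntheta is not None else cfg["ntheta"],
        R=load_defaults()["params"]["R"],
        ap_angle=np.deg2rad(cfg["ap_angle_deg"]),
    )


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursive dict merge (override wins), returning a new dict."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out
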