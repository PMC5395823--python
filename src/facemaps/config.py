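"""Pipeline configuration (YAML) and provenance records.

A pipeline config is a YAML mapping with an optional ``seed`` and one block
per stage, executed in the fixed order simulate -> align -> gessa ->
curvature -> traits -> heritability -> maps.  Unknown stages or fields are
reported with their full field path so typos surface immediately.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import yaml

__all__ = ["load_config", "validate_config", "write_provenance", "STAGE_ORDER"]

STAGE_ORDER = ("simulate", "align", "gessa", "curvature", "traits",
               "heritability", "maps")

_SCHEMA = {
    "simulate": {
        "out": str, "n_mz": int, "n_dz": int, "subdivisions": int,
        "h2": float, "c2": float, "amp_sd": float, "bump_index": int,
        "noise_sd": float,
    },
    "align": {"meshes": str, "reference": str, "out": str,
              "max_iters": int, "tol": float},
    "gessa": {"meshes": str, "out": str, "M": int, "iters_per_level": int,
              "gamma_scale": float, "alpha_scale": float, "epsilon": float,
              "tol": float, "weight_corr": float, "steiner_per_edge": int},
    "curvature": {"meshes": str, "landmarks": str, "out": str, "radius": float},
    "traits": {"meshes": str, "landmarks": str, "picks": str, "out": str,
               "mode": str},
    "heritability": {"traits": str, "pairs": str, "out": str, "use_age": bool},
    "maps": {"results": str, "mesh": str, "landmarks": str, "out": str,
             "mask_failing": bool},
}

_REQUIRED = {
    "simulate": ("out",),
    "align": ("meshes", "reference", "out"),
    "gessa": ("meshes", "out", "M"),
    "curvature": ("meshes", "landmarks", "out"),
    "traits": ("meshes", "landmarks", "picks", "out"),
    "heritability": ("traits", "pairs", "out"),
    "maps": ("results", "mesh", "landmarks", "out"),
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    known_top = set(STAGE_ORDER) | {"seed"}
    for key in cfg:
        if key not in known_top:
            raise ConfigError(f"unknown top-level field {key!r}"
                              f" (expected one of {sorted(known_top)})")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        raise ConfigError("seed: expected an integer")
    for stage in STAGE_ORDER:
        if stage not in cfg:
            continue
        block = cfg[stage]
        if not isinstance(block, dict):
            raise ConfigError(f"{stage}: expected a mapping of options")
        schema = _SCHEMA[stage]
        for field, value in block.items():
            if field not in schema:
                raise ConfigError(f"{stage}.{field}: unknown field")
            want = schema[field]
            if want is float and isinstance(value, int):
                value = float(value)
            if not isinstance(value, want):
                raise ConfigError(
                    f"{stage}.{field}: expected {want.__name__},"
                    f" got {type(value).__name__}")
        for field in _REQUIRED[stage]:
            if field not in block:
                raise ConfigError(f"{stage}.{field}: required field missing")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg or {})


def write_provenance(out_dir, stage: str, params: dict, seed=None):
    """JSON record of what a stage ran with, for reproducibility audits."""
    from . import __version__

    rec = {
        "stage": stage,
        "parameters": {k: str(v) if isinstance(v, Path) else v
                       for k, v in params.items()},
        "seed": seed,
        "facemaps_version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"provenance_{stage}.json", "w") as fh:
        json.dump(rec, fh, indent=2)
    return rec
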