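"""Run configuration: defaults, schema validation, hashing."""

from __future__ import annotations

import copy
import hashlib
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["default_config", "validate_config", "load_config", "config_hash"]


def default_config() -> dict:
    """The demo configuration: 150x150 grid, 21 years, all knobs explicit."""
    return {
        "seed": 1,
        "grid": {"n_rows": 150, "n_cols": 150, "cell_size": 250.0, "nodata_value": -9999.0},
        "years": {"start": 2000, "end": 2020},
        "landscape": {
            "proportions_start": {
                "cropland": 0.62,
                "forest": 0.12,
                "grassland": 0.10,
                "water": 0.04,
                "urban": 0.07,
                "unused": 0.05,
            },
            "proportions_end": {
                "cropland": 0.55,
                "forest": 0.10,
                "grassland": 0.08,
                "water": 0.04,
                "urban": 0.18,
                "unused": 0.05,
            },
            "clumping": 0.6,
        },
        "forcing": {
            "ppt": {"mean": 750.0, "sd": 110.0, "spatial_gradient": 0.25, "trend": 3.0},
            "tem": {"mean": 12.5, "sd": 1.2, "spatial_gradient": 0.15, "trend": 0.02},
            "sol": {"mean": 45.0, "sd": 3.0, "spatial_gradient": 0.05, "trend": 0.0},
            "ndvi_coupling": 0.7,
        },
        "zones": {"rows": 2, "cols": 2, "base_yield_t_ha": 5.0, "yield_trend_t_ha": 0.08},
        "es": {"z": 7.5},
        "constraint": {
            "n_bins": 50,
            "quantile": 0.99,
            "min_points": 10,
            "sample_n": 10000,
            "forms": {"SC_FP": "exponential"},
            "default_form": "hump",
        },
        "metrics": {"connectivity": 8},
        "drivers": {"max_terms": 6, "vif_cap": 10.0, "min_aicc_drop": 6.0},
        "output": {"write_rasters": True},
    }


def _check_keys(cfg: dict, schema: dict, path: str = "") -> None:
    for key, value in cfg.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown configuration key: {here}")
        sub = schema[key]
        if isinstance(sub, dict) and sub:
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            _check_keys(value, sub, here)


# schema = the default's key tree; leaves that accept free-form mappings
# (class proportions, per-pair form overrides) are marked open with {}.
def _schema() -> dict:
    def tree(d: dict) -> dict:
        return {k: tree(v) if isinstance(v, dict) else None for k, v in d.items()}

    s = tree(default_config())
    s["landscape"]["proportions_start"] = {}
    s["landscape"]["proportions_end"] = {}
    s["constraint"]["forms"] = {}
    s["years"] = None  # mapping {start, end} or an explicit list; checked below
    return s


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def validate_config(cfg: dict) -> dict:
    """Merge onto defaults, reject unknown keys, resolve the year list."""
    _check_keys(cfg, _schema())
    merged = _merge(default_config(), cfg)
    years = merged["years"]
    if isinstance(years, dict):
        extra = set(years) - {"start", "end"}
        if extra:
            raise ConfigError(f"unknown keys under years: {sorted(extra)}")
        merged["years"] = list(range(int(years["start"]), int(years["end"]) + 1))
    else:
        merged["years"] = [int(y) for y in years]
    if not merged["years"]:
        raise ConfigError("years must be non-empty")
    return merged


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file (or the defaults when path is None) and validate."""
    if path is None:
        return validate_config({})
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config file must hold a mapping")
    return validate_config(cfg)


def config_hash(cfg: dict) -> str:
    """Stable sha256 of the fully resolved configuration."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
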