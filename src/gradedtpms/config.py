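"""YAML run-configuration parsing and validation.

Physical quantities carry explicit unit suffixes at the config boundary
(``domain_mm``, ``flow_rate_lpm``, ...) and are converted to SI internally.
Validation reports the offending key by name; the CLI maps
:class:`ConfigError` to exit code 2.
"""

from __future__ import annotations

from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration key is missing or invalid."""


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def require(cfg: dict, key: str, typ=None, section: str = ""):
    where = f"{section}.{key}" if section else key
    if key not in cfg:
        raise ConfigError(f"missing required config key: {where}")
    val = cfg[key]
    if typ is not None and not isinstance(val, typ):
        raise ConfigError(f"config key {where} must be of type {typ}, got {type(val).__name__}")
    return val


def positive(cfg: dict, key: str, default=None, section: str = "") -> float:
    if default is not None and key not in cfg:
        return float(default)
    val = require(cfg, key, section=section)
    try:
        val = float(val)
    except (TypeError, ValueError):
        raise ConfigError(f"config key {key} must be numeric") from None
    if not val > 0:
        raise ConfigError(f"config key {key} must be > 0, got {val}")
    return val


def triple(cfg: dict, key: str, section: str = "") -> tuple[float, float, float]:
    val = require(cfg, key, section=section)
    if not isinstance(val, (list, tuple)) or len(val) != 3:
        raise ConfigError(f"config key {key} must be a list of 3 numbers")
    return tuple(float(v) for v in val)


def lpm_to_m3s(lpm: float) -> float:
    return lpm / 60.0e3


DESIGN_DEFAULTS = {
    "cs_min_mm": 1.2,
    "cs_init_mm": 1.2,
    "offset_c": 0.0,
    "control_spacing_mm": None,   # default: domain/4
    "kernel_width_mm": None,      # default: control spacing
}

FLOW_DEFAULTS = {
    "flow_rate_lpm": 0.5,
    "viscosity_pas": 1.0e-3,
    "density_kgm3": 998.0,
    "porosity": 0.5,
    "bolus_duration_s": 2.0,
    "frame_dt_s": 0.5,
    "phi_max": 0.2,
    "d0": 1.0e9,
    "f0": 1.0e4,
    "cs0_mm": 1.2,
}

ANALYSIS_DEFAULTS = {
    "sd_max_percent": 10.0,
    "target_edge_mm": 2.0,
    "corner_frac": 0.35,
    "up_axis": 1,
}
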