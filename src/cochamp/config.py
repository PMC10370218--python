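"""Configuration handling: embedded defaults, TOML overrides, builders.

One human-readable TOML file with sections [chain], [geometry],
[partition], [solver], [cochlea2d], [noise] and [snr]; every field has an
embedded default (the calibrated model), and the merged configuration is
echoed into the run manifest.  Exit-code conventions for the CLI:
0 success, 2 configuration error, 3 solver failure.
"""

from __future__ import annotations

import copy
import tomllib
from pathlib import Path
from typing import Any

from .chain import ChainConfig
from .cochlea2d import Cochlea2DConfig, Cochlea2DModel
from .waveguide import CochlearGeometry, CochlearModel, PartitionModel

__all__ = ["DEFAULTS", "load_config", "ConfigError", "build_model", "build_model_2d", "build_chain"]


class ConfigError(ValueError):
    """Invalid configuration with a field-level message."""


DEFAULTS: dict[str, dict[str, Any]] = {
    "chain": {
        "num_nodes": 10,
        "gain": 1.0,
        "noise_strength": 1.0,
        "signal_rms_in": 1.0,
        "trials": 10_000,
        "seed": 0,
    },
    "geometry": {
        "length": 5e-3,  # m
        "height": 0.5e-3,  # m
        "grid": 1024,
        "area_base": 2.5e-7,  # m^2
        "area_taper": 0.0,
    },
    "partition": {
        "cf_base": 70e3,  # Hz
        "cf_apex": 4e3,  # Hz
        "fluid_mass_density": 4.0e6,  # kg/m^4
        "partition_mass": 4.0e6 / 17000.0**2,  # kg/m^2
        "damping_active": -0.08,
        "damping_passive": 0.20,
        "activity_steepness": 16.0,
        "activity_center": 1.0,
        "onset_length": 0.4e-3,  # m
        "helicotrema_damping": 3.0,
        "helicotrema_length": 0.5e-3,  # m
    },
    "solver": {
        "provider": "wkb",  # wkb | fd1d | fd2d
        "min_points_per_wavelength": 20.0,
    },
    "cochlea2d": {
        "stapes_reflectance": 0.0,
        "grid_nx": 768,
        "grid_ny": 48,
    },
    "noise": {
        "mu": 1.0,
        "sigma": 0.0,
        "law": "rayleigh",
        "realizations": 200,
        "seed": 0,
    },
    "snr": {
        "band_low": 4e3,  # Hz
        "band_high": 70e3,  # Hz
        "num_freqs_broadband": 64,
        "num_freqs_narrowband": 33,
        "gain_fraction": 0.5,  # near-base flag threshold on CF signal gain
        "apical_margin": 0.25e-3,  # m, absorbing-termination exclusion
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in out:
            raise ConfigError(f"unknown configuration field: {where}")
        if isinstance(out[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{where} must be a table")
            out[key] = _merge(out[key], val, where)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Merged configuration: embedded defaults overridden by a TOML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    return _merge(DEFAULTS, user)


def build_model(cfg: dict) -> CochlearModel:
    try:
        geo = CochlearGeometry(**cfg["geometry"])
        part = PartitionModel(**cfg["partition"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return CochlearModel(geo, part)


def build_model_2d(cfg: dict) -> Cochlea2DModel:
    try:
        geo = CochlearGeometry(**cfg["geometry"])
        part = PartitionModel(**cfg["partition"])
        c2 = Cochlea2DConfig(geometry=geo, partition=part, **cfg["cochlea2d"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return Cochlea2DModel(c2)


def build_chain(cfg: dict) -> ChainConfig:
    c = cfg["chain"]
    try:
        return ChainConfig(
            num_nodes=c["num_nodes"],
            gain=c["gain"],
            noise_strength=c["noise_strength"],
            signal_rms_in=c["signal_rms_in"],
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def validate_band(cfg: dict) -> tuple[float, float]:
    lo, hi = cfg["snr"]["band_low"], cfg["snr"]["band_high"]
    p = cfg["partition"]
    if lo < p["cf_apex"] or hi > p["cf_base"]:
        raise ConfigError(
            f"analysis band {lo / 1e3:g}-{hi / 1e3:g} kHz exceeds the CF map "
            f"limits {p['cf_apex'] / 1e3:g}-{p['cf_base'] / 1e3:g} kHz"
        )
    return float(lo), float(hi)
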