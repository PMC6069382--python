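"""Flat key-value configuration for the simulator.

A run is configured by a single flat YAML mapping; every key has a
built-in default carrying the reference proof-of-concept constants
(tomato-firmness kinetics, ±2 °C / ±3.5 %RH sensor accuracies, ts = 300 s,
a 5 × 5 lattice over 6.3 × 6.7 m, and the displacement-trigger presets).
Unknown keys are rejected by name.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .envfield import IsdStudyConfig, LatticeSpec
from .kinetics import KineticParams
from .monitor import CTH_PRESETS, MonitorConfig
from .synthdata import EnvProfileSpec

__all__ = [
    "ConfigError",
    "DEFAULTS",
    "load_config",
    "kinetic_params_from_config",
    "monitor_config_from_config",
    "lattice_from_config",
    "env_spec_from_config",
    "isd_study_from_config",
]


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    # kinetics (tomato-firmness preset)
    "k_ref_per_day": 0.2,
    "T_ref_C": 20.0,
    "Ea_kJ_per_mol": 64.8,
    "c0_N": 12.4,
    "c_eq_N": 3.0,
    "product_label": "tomato-firmness",
    # monitoring loop
    "ts_s": 300.0,
    "T_store_ref_C": 20.0,
    "H_ref_pct": 55.0,
    "L_ref_lux": 500.0,
    "T_th_C": 2.0,
    "H_th_pct": 3.5,
    "L_th_lux": 100.0,
    "c_th_preset": "24C",  # one of CTH_PRESETS, or override c_th_N_per_s
    "c_th_N_per_s": None,
    # lattice / room
    "lattice_M1": 5,
    "lattice_M2": 5,
    "room_l1_m": 6.3,
    "room_l2_m": 6.7,
    # synthetic environment
    "duration_h": 24.0,
    "dt_s": 300.0,
    "start_hour": 8.0,
    "base_mean_C": 21.3,
    "base_sd_C": 0.5,
    "diurnal_amp_C": 1.5,
    "window_sensor_ids": ["S1", "S2"],
    "overheat_mean_C": 2.8,
    "overheat_sd_C": 0.8,
    "relax_rate_C_per_h": 0.1,
    "rh_mean_pct": 55.73,
    "rh_sd_pct": 1.5,
    "rh_coupling_pct_per_C": -2.5 / 3.0,
    "T_noise_C": 2.0,
    "RH_noise_pct": 3.5,
    "lux_day": 500.0,
    "lux_night": 5.0,
    "battery_drain_pct_per_day": 1.0,
    "flag_fail_prob": 0.0,
    # Isd characterization
    "isd_values_m": [1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5],
    "isd_reps": 16,
    "isd_grad_x_C_per_m": 0.8,
    "isd_grad_y_C_per_m": 0.3,
    "isd_noise_T_C": 0.0,
    "isd_noise_RH_pct": 0.0,
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML config file over the defaults; reject unknown keys."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a flat mapping")
    for key, value in raw.items():
        if key not in DEFAULTS:
            raise ConfigError(f"unknown configuration key: {key!r}")
        cfg[key] = value
    return cfg


def kinetic_params_from_config(cfg: dict) -> KineticParams:
    return KineticParams(
        k_ref=float(cfg["k_ref_per_day"]),
        T_ref_C=float(cfg["T_ref_C"]),
        Ea=float(cfg["Ea_kJ_per_mol"]),
        c0=float(cfg["c0_N"]),
        c_eq=float(cfg["c_eq_N"]),
        product_label=str(cfg["product_label"]),
    )


def monitor_config_from_config(cfg: dict) -> MonitorConfig:
    c_th = cfg["c_th_N_per_s"]
    if c_th is None:
        preset = cfg["c_th_preset"]
        if preset not in CTH_PRESETS:
            raise ConfigError(
                f"unknown c_th_preset {preset!r}; choose from {sorted(CTH_PRESETS)}"
            )
        c_th = CTH_PRESETS[preset]
    return MonitorConfig(
        ts=float(cfg["ts_s"]),
        T_ref=float(cfg["T_store_ref_C"]),
        H_ref=float(cfg["H_ref_pct"]),
        L_ref=float(cfg["L_ref_lux"]),
        T_th=float(cfg["T_th_C"]),
        H_th=float(cfg["H_th_pct"]),
        L_th=float(cfg["L_th_lux"]),
        C_th=float(c_th),
    )


def lattice_from_config(cfg: dict) -> LatticeSpec:
    return LatticeSpec(
        M1=int(cfg["lattice_M1"]),
        M2=int(cfg["lattice_M2"]),
        l1=float(cfg["room_l1_m"]),
        l2=float(cfg["room_l2_m"]),
    )


def env_spec_from_config(cfg: dict, seed: int | None = None) -> EnvProfileSpec:
    return EnvProfileSpec(
        duration_h=float(cfg["duration_h"]),
        dt_s=float(cfg["dt_s"]),
        start_hour=float(cfg["start_hour"]),
        base_mean=float(cfg["base_mean_C"]),
        base_sd=float(cfg["base_sd_C"]),
        diurnal_amp=float(cfg["diurnal_amp_C"]),
        window_sensor_ids=tuple(cfg["window_sensor_ids"]),
        overheat_mean=float(cfg["overheat_mean_C"]),
        overheat_sd=float(cfg["overheat_sd_C"]),
        relax_rate=float(cfg["relax_rate_C_per_h"]),
        rh_mean=float(cfg["rh_mean_pct"]),
        rh_sd=float(cfg["rh_sd_pct"]),
        rh_coupling=float(cfg["rh_coupling_pct_per_C"]),
        T_noise=float(cfg["T_noise_C"]),
        RH_noise=float(cfg["RH_noise_pct"]),
        lux_day=float(cfg["lux_day"]),
        lux_night=float(cfg["lux_night"]),
        battery_drain=float(cfg["battery_drain_pct_per_day"]),
        flag_fail_prob=float(cfg["flag_fail_prob"]),
        seed=int(cfg["seed"] if seed is None else seed),
    )


def isd_study_from_config(cfg: dict) -> IsdStudyConfig:
    return IsdStudyConfig(
        base_T=float(cfg["base_mean_C"]),
        grad_x=float(cfg["isd_grad_x_C_per_m"]),
        grad_y=float(cfg["isd_grad_y_C_per_m"]),
        rh_mean=float(cfg["rh_mean_pct"]),
        rh_coupling=float(cfg["rh_coupling_pct_per_C"]),
        T_noise_acc=float(cfg["isd_noise_T_C"]),
        RH_noise_acc=float(cfg["isd_noise_RH_pct"]),
    )
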