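"""Seeded synthetic sensor logs and scenarios for the storage room.

Replaces the physical monitoring campaign: generates per-node temperature,
relative humidity, illuminance, battery and working-flag time series with
the statistical structure observed in a non-refrigerated room —

* latent room temperature: base mean 21.3 °C with a diurnal sinusoid and
  AR(1) jitter (combined spread ≈ 1.2 °C);
* window-side nodes gain a 9:00–16:00 solar-irradiation ramp whose daily
  peak is drawn from N(2.8, 0.8) °C, relaxing back at ≈ 0.1 °C/h;
* relative humidity ≈ 55.73 %, inversely coupled to temperature at
  −2.5 % per +3 °C;
* reported readings add measurement noise bounded by the sensor
  accuracies (±2 °C, ±3.5 %RH), realised as N(0, acc/2) clipped at ±acc;
* illuminance is a day/night square wave inside the 1–1000 lux sensor
  range; battery drains linearly; the working flag may toggle randomly.

Everything is deterministic given the seed.  The module also ships the
reference proof-of-concept scenario: a 6.3 × 6.7 m room on a 5 × 5
lattice with 8 wall sensors and 4 managed pallets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .envfield import LatticeSpec, SensorNode, map_sensors_to_cells
from .kinetics import TOMATO_FIRMNESS, KineticParams, quality_trajectory
from .monitor import MonitorConfig, init_pallet
from .qcl import Pallet, PalletRegistry

__all__ = [
    "EnvProfileSpec",
    "Scenario",
    "generate_room",
    "generate_firmness_series",
    "table3_scenario",
]


@dataclass(frozen=True)
class EnvProfileSpec:
    """Statistical profile of the synthetic storage room."""

    duration_h: float = 251.0  # 10 days 11 h
    dt_s: float = 300.0
    start_hour: float = 8.0  # clock time of the first sample
    base_mean: float = 21.3  # °C
    base_sd: float = 0.5  # °C, marginal sd of the AR(1) jitter
    diurnal_amp: float = 1.5  # °C, sinusoid amplitude (peak ~15:00)
    window_sensor_ids: tuple[str, ...] = ("S1", "S2")
    overheat_mean: float = 2.8  # °C, daily window-ramp peak
    overheat_sd: float = 0.8  # °C
    relax_rate: float = 0.1  # °C/h decay of the ramp excess after 16:00
    rh_mean: float = 55.73  # %
    rh_sd: float = 1.5  # %, marginal sd of the RH jitter
    rh_coupling: float = -2.5 / 3.0  # %RH per °C
    T_noise: float = 2.0  # °C measurement-noise bound
    RH_noise: float = 3.5  # %RH measurement-noise bound
    lux_day: float = 500.0
    lux_night: float = 5.0
    battery_drain: float = 1.0  # %/day
    flag_fail_prob: float = 0.0  # per-sample probability of a working=0 toggle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        for name in ("base_sd", "overheat_sd", "rh_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (1 <= self.lux_night <= 1000 and 1 <= self.lux_day <= 1000):
            raise ValueError("lux levels must lie within the 1-1000 lux sensor range")


def _ar1(rng: np.random.Generator, n: int, marginal_sd: float, dt_h: float,
         corr_time_h: float = 1.0) -> np.ndarray:
    """AR(1) series with the given marginal sd and ~1 h correlation time."""
    if marginal_sd == 0:
        return np.zeros(n)
    phi = math.exp(-dt_h / corr_time_h)
    eps_sd = marginal_sd * math.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], rng.normal(0.0, eps_sd, n))


def _bounded_noise(rng: np.random.Generator, acc: float, n: int) -> np.ndarray:
    if acc <= 0:
        return np.zeros(n)
    return np.clip(rng.normal(0.0, acc / 2.0, n), -acc, acc)


def _window_excess(rng: np.random.Generator, abs_h: np.ndarray,
                   spec: EnvProfileSpec) -> np.ndarray:
    """Solar-overheating excess for a window-adjacent node.

    Each day contributes a ramp rising linearly 9:00→16:00 to a random
    peak, then decaying at ``relax_rate``; contributions from successive
    days are merged by elementwise max (the slow relaxation can straddle
    midnight).
    """
    n_days = int(math.ceil((abs_h[-1]) / 24.0)) + 1
    excess = np.zeros_like(abs_h)
    for d in range(n_days):
        peak = max(0.0, rng.normal(spec.overheat_mean, spec.overheat_sd))
        t9 = d * 24.0 + 9.0
        t16 = d * 24.0 + 16.0
        contrib = np.where(
            abs_h < t9,
            0.0,
            np.where(
                abs_h < t16,
                peak * (abs_h - t9) / 7.0,
                np.maximum(0.0, peak - spec.relax_rate * (abs_h - t16)),
            ),
        )
        excess = np.maximum(excess, contrib)
    return excess


def generate_room(
    spec: EnvProfileSpec, sensors: list[SensorNode]
) -> pd.DataFrame:
    """Generate the full per-node sensor log as a tidy DataFrame.

    Columns: ``time_s``, ``time_h``, ``node_id``, ``T_C``, ``RH_pct``,
    ``lux``, ``battery_pct``, ``working``, plus the latent (noise-free)
    ``T_latent_C`` for validation.  Deterministic given ``spec.seed``.
    """
    known = {s.node_id for s in sensors}
    unknown = set(spec.window_sensor_ids) - known
    if unknown:
        raise ValueError(f"window sensor ids not in the sensor list: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    t_s = np.arange(0.0, spec.duration_h * 3600.0 + 0.5 * spec.dt_s, spec.dt_s)
    t_h = t_s / 3600.0
    abs_h = spec.start_hour + t_h  # absolute clock hours since day-0 midnight
    hod = abs_h % 24.0
    dt_h = spec.dt_s / 3600.0
    n = t_s.size
    diurnal = spec.diurnal_amp * np.sin(2.0 * np.pi * (hod - 9.0) / 24.0)
    lux_base = np.where((hod >= 8.0) & (hod < 20.0), spec.lux_day, spec.lux_night)
    frames = []
    for s in sensors:
        jitter = _ar1(rng, n, spec.base_sd, dt_h)
        latent = spec.base_mean + diurnal + jitter
        if s.node_id in spec.window_sensor_ids:
            latent = latent + _window_excess(rng, abs_h, spec)
        T_read = latent + _bounded_noise(rng, min(spec.T_noise, s.T_acc), n)
        rh_latent = (
            spec.rh_mean
            + spec.rh_coupling * (latent - spec.base_mean)
            + _ar1(rng, n, spec.rh_sd, dt_h)
        )
        RH_read = rh_latent + _bounded_noise(rng, min(spec.RH_noise, s.RH_acc), n)
        lux = np.clip(lux_base, 1.0, 1000.0)
        battery = np.clip(100.0 - spec.battery_drain * t_h / 24.0, 0.0, 100.0)
        working = np.ones(n, dtype=int)
        if spec.flag_fail_prob > 0:
            working = (rng.random(n) >= spec.flag_fail_prob).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t_s,
                    "time_h": t_h,
                    "node_id": s.node_id,
                    "T_C": T_read,
                    "RH_pct": RH_read,
                    "lux": lux,
                    "battery_pct": battery,
                    "working": working,
                    "T_latent_C": latent,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_firmness_series(
    params: KineticParams,
    t_days,
    T_C,
    noise_sd: float = 0.02,
    seed: int = 0,
    form: str = "exponential",
) -> pd.DataFrame:
    """Observed (t, c) firmness series along a temperature trajectory.

    Integrates the first-order decay with piecewise-constant rates over
    the sampling intervals and applies seeded multiplicative noise of
    standard deviation ``noise_sd`` (0 = exact closed-form curve).
    """
    t = np.asarray(t_days, dtype=float)
    if t.size == 0:
        raise ValueError("time series must be non-empty")
    c = quality_trajectory(params, t, np.asarray(T_C, dtype=float), form=form)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = c * (1.0 + rng.normal(0.0, noise_sd, c.shape))
    return pd.DataFrame({"t_day": t, "c_N": c})


@dataclass
class Scenario:
    """A ready-to-run warehouse scenario (lattice + sensors + pallets)."""

    lattice: LatticeSpec
    sensors: list[SensorNode]
    registry: PalletRegistry
    pallet_coords_m: dict[int, tuple[float, float]] = dc_field(default_factory=dict)


#: Printed wall-sensor positions of the reference proof-of-concept room.
REFERENCE_SENSOR_POSITIONS = {
    "S1": (1.26, 0.0),
    "S2": (3.78, 0.0),
    "S3": (0.0, 1.34),
    "S4": (0.0, 4.02),
    "S5": (1.26, 6.7),
    "S6": (3.78, 6.7),
    "S7": (6.3, 1.34),
    "S8": (6.3, 4.02),
}

#: Printed initial pallet coordinates (m) of the reference 4-pallet run.
REFERENCE_PALLET_COORDS = {
    1: (1.26, 0.0),
    2: (2.52, 2.68),
    3: (1.26, 5.36),
    4: (3.78, 0.0),
}


def table3_scenario(
    params: KineticParams = TOMATO_FIRMNESS,
    config: MonitorConfig | None = None,
) -> Scenario:
    """The reference scenario: 6.3 × 6.7 m room, 5 × 5 lattice, 8 wall
    sensors and 4 tomato pallets at their printed initial coordinates."""
    config = config or MonitorConfig()
    lattice = LatticeSpec(M1=5, M2=5, l1=6.3, l2=6.7)
    sensors = [
        SensorNode(node_id=nid, x=x, y=y)
        for nid, (x, y) in REFERENCE_SENSOR_POSITIONS.items()
    ]
    map_sensors_to_cells(lattice, sensors)
    pallets = []
    for pid, (x, y) in REFERENCE_PALLET_COORDS.items():
        i = min(int(math.floor(y / lattice.cell_dy + 1e-9)), lattice.M1 - 1)
        j = min(int(math.floor(x / lattice.cell_dx + 1e-9)), lattice.M2 - 1)
        pallets.append(
            Pallet(
                pallet_id=pid,
                cell=(i, j),
                state=init_pallet(params, config),
                params=params,
            )
        )
    registry = PalletRegistry(pallets=pallets, lattice_shape=lattice.shape)
    return Scenario(
        lattice=lattice,
        sensors=sensors,
        registry=registry,
        pallet_coords_m=dict(REFERENCE_PALLET_COORDS),
    )
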