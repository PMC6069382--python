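"""Periodic monitoring/control loop for one monitored pallet.

Every ``ts`` seconds the loop reads temperature, relative humidity and
illuminance, compares each against its recommended storage value within a
symmetric band (reference ± accuracy-derived half-width), raises one flag
per violated band, and advances the pallet's quality and shelf life by one
sampling interval.  Only the temperature test selects the decay rate: when
the temperature is inside its band the reference rate k_ref applies;
otherwise the Arrhenius rate at the measured temperature.  Humidity and
light violations raise warning flags only — corrective action for those is
left to a human operator.  The loop runs while the predicted shelf life is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import (
    KineticParams,
    QualityState,
    arrhenius_rate,
    decay_step,
    shelf_life,
    shelf_life_bounds,
)

__all__ = [
    "SECONDS_PER_DAY",
    "CTH_PRESETS",
    "MonitorConfig",
    "FlagSet",
    "MonitorResult",
    "MonitorTerminated",
    "init_pallet",
    "monitor_step",
    "run_monitor",
]

SECONDS_PER_DAY = 86_400.0

#: Preset per-second firmness-decrease triggers for pallet displacement,
#: stored verbatim (N/s over a 10-min interval at the quoted temperature).
CTH_PRESETS = {"24C": 2.68e-5, "26C": 3.184e-5}


class MonitorTerminated(RuntimeError):
    """Raised when the loop is stepped after the shelf life reached zero."""


@dataclass(frozen=True)
class MonitorConfig:
    """Monitoring-loop configuration.

    ``ts`` is the sampling interval in seconds (default 300 s = one read
    per 5 min).  The reference values are the recommended storage
    conditions; the ``_th`` half-widths derive from the sensor accuracies
    (±2 °C, ±3.5 %RH, ±20 % on illuminance).
    """

    ts: float = 300.0  # s
    T_ref: float = 20.0  # °C
    H_ref: float = 55.0  # %RH
    L_ref: float = 500.0  # lux
    T_th: float = 2.0  # °C
    H_th: float = 3.5  # %RH
    L_th: float = 100.0  # lux
    C_th: float = CTH_PRESETS["24C"]  # N/s, displacement trigger

    def __post_init__(self) -> None:
        if self.ts <= 0:
            raise ValueError(f"sampling interval must be positive, got {self.ts}")
        for name in ("T_th", "H_th", "L_th", "C_th"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FlagSet:
    """Intervention-request flags raised at one monitoring tick."""

    temp_flag: bool = False
    hum_flag: bool = False
    light_flag: bool = False
    battery_flag: bool = False
    working_flag: bool = False
    timestamp: float = 0.0  # elapsed time, day

    @property
    def any(self) -> bool:
        return (
            self.temp_flag
            or self.hum_flag
            or self.light_flag
            or self.battery_flag
            or self.working_flag
        )


def init_pallet(params: KineticParams, config: MonitorConfig) -> QualityState:
    """Initial state: c = c0, rate = k_ref, SL from the reference rate."""
    sl0 = shelf_life(params.c0, params, params.k_ref)
    return QualityState(t=0.0, c=params.c0, k_current=params.k_ref, SL=sl0)


def monitor_step(
    state: QualityState,
    reading: tuple[float, float, float],
    config: MonitorConfig,
    params: KineticParams,
    form: str = "exponential",
) -> tuple[QualityState, FlagSet]:
    """One sampling tick: threshold tests, rate selection, quality/SL update.

    ``reading`` is (T °C, H %RH, L lux).  A flag is raised per violated
    band; the decay rate is k_ref if the temperature is in band, else the
    Arrhenius rate at the measured temperature (humidity/light never alter
    the rate).  Shelf-life bounds use the temperature half-width as the
    sensor accuracy.
    """
    if state.SL <= 0:
        raise MonitorTerminated("shelf life exhausted; the monitoring loop has ended")
    T, H, L = reading
    temp_ok = abs(T - config.T_ref) <= config.T_th
    hum_ok = abs(H - config.H_ref) <= config.H_th
    light_ok = abs(L - config.L_ref) <= config.L_th
    k = params.k_ref if temp_ok else arrhenius_rate(params, T)
    dt = config.ts / SECONDS_PER_DAY
    new = decay_step(state, params, k, dt, form=form)
    if new.c > params.c_eq:
        lo, hi = shelf_life_bounds(new.c, params, T, config.T_th)
    else:
        lo = hi = 0.0
    new = QualityState(t=new.t, c=new.c, k_current=k, SL=new.SL, SL_lo=lo, SL_hi=hi)
    flags = FlagSet(
        temp_flag=not temp_ok,
        hum_flag=not hum_ok,
        light_flag=not light_ok,
        timestamp=new.t,
    )
    return new, flags


@dataclass
class MonitorResult:
    """Trajectory of states (including the initial one) and the flag log."""

    states: list[QualityState]
    flags: list[FlagSet]

    @property
    def expiry_time(self) -> float | None:
        """Elapsed time (day) at which SL first reached zero, if it did."""
        for s in self.states:
            if s.SL <= 0:
                return s.t
        return None


def run_monitor(
    state0: QualityState,
    readings,
    config: MonitorConfig,
    params: KineticParams,
    form: str = "exponential",
) -> MonitorResult:
    """Iterate the loop over a reading series until SL = 0 or exhaustion.

    Readings are (T, H, L) tuples sampled at ``ts``; a ``None`` entry
    (missing transmission) carries the previous reading forward and raises
    the working flag for that tick.
    """
    readings = list(readings)
    if not readings:
        raise ValueError("reading series must be non-empty")
    states = [state0]
    flags: list[FlagSet] = []
    last = None
    for reading in readings:
        if states[-1].SL <= 0:
            break
        missing = reading is None
        if missing:
            if last is None:
                raise ValueError("first reading of the series is missing")
            reading = last
        last = reading
        new, f = monitor_step(states[-1], reading, config, params, form=form)
        if missing:
            f = FlagSet(
                temp_flag=f.temp_flag,
                hum_flag=f.hum_flag,
                light_flag=f.light_flag,
                working_flag=True,
                timestamp=f.timestamp,
            )
        states.append(new)
        flags.append(f)
    return MonitorResult(states=states, flags=flags)
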