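"""First-order Arrhenius kinetics for perishable-produce quality decay.

The quality of a stored perishable product (here: tomato firmness, in
newtons) is tracked by a single scalar quality factor ``c`` that decays
towards an equilibrium/failure level ``c_eq`` with a first-order rate
constant ``k``.  The temperature dependence of ``k`` follows the Arrhenius
law in its ratio form,

    k(T) = k_ref * exp(-(Ea/R) * (1/T - 1/T_ref)),

with absolute temperatures, activation energy ``Ea`` and the rate at a
reference temperature ``k_ref``.  The remaining shelf life of a product
whose current quality is ``c'`` is

    SL = (1/k) * ln(c' / c_eq),

i.e. the time left until the quality factor crosses the failure level at
the current rate.  Because temperature sensors have a finite accuracy
``±acc``, the rate — and hence the shelf life — is only known within an
interval: the pessimistic rate is evaluated at ``T + acc`` and the
optimistic one at ``T - acc``.

All public interfaces take temperatures in degrees Celsius and rates in
day⁻¹; conversions to kelvin happen internally with R = 8.314 J mol⁻¹ K⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "R_GAS",
    "KELVIN_OFFSET",
    "KineticParams",
    "QualityState",
    "RateFit",
    "TOMATO_FIRMNESS",
    "arrhenius_rate",
    "rate_bounds",
    "decay_step",
    "shelf_life",
    "shelf_life_bounds",
    "quality_trajectory",
    "fit_rate",
]

R_GAS = 8.314  # J mol^-1 K^-1
KELVIN_OFFSET = 273.15
ABSOLUTE_ZERO_C = -KELVIN_OFFSET

_DECAY_FORMS = ("exponential", "equilibrium")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameter set governing first-order quality decay.

    Parameters
    ----------
    k_ref : float
        Rate constant at the reference temperature (day⁻¹).
    T_ref_C : float
        Reference temperature (°C).
    Ea : float
        Activation energy (kJ/mol).
    c0 : float
        Initial quality factor (N).
    c_eq : float
        Equilibrium / failure quality factor (N).
    W : float, optional
        Pre-exponential factor (day⁻¹) of the absolute Arrhenius form;
        informational only — all rate evaluations use the ratio form.
    product_label : str
        Free-text product description.
    """

    k_ref: float
    T_ref_C: float
    Ea: float
    c0: float
    c_eq: float
    W: float | None = None
    product_label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k_ref) and self.k_ref > 0):
            raise ValueError(f"k_ref must be positive, got {self.k_ref}")
        if not (math.isfinite(self.Ea) and self.Ea > 0):
            raise ValueError(f"Ea must be positive, got {self.Ea}")
        if self.T_ref_C <= ABSOLUTE_ZERO_C:
            raise ValueError(f"T_ref_C must exceed absolute zero, got {self.T_ref_C}")
        if not (self.c0 > self.c_eq >= 0):
            raise ValueError(
                f"require c0 > c_eq >= 0, got c0={self.c0}, c_eq={self.c_eq}"
            )

    @property
    def T_ref_K(self) -> float:
        return self.T_ref_C + KELVIN_OFFSET


#: Tomato-firmness preset: firmness decay rate 0.2 day⁻¹ at 20 °C,
#: Ea = 64.8 kJ/mol, initial firmness 12.4 N, failure firmness 3 N.
TOMATO_FIRMNESS = KineticParams(
    k_ref=0.2,
    T_ref_C=20.0,
    Ea=64.8,
    c0=12.4,
    c_eq=3.0,
    product_label="tomato-firmness",
)


@dataclass(frozen=True)
class QualityState:
    """Instantaneous quality/shelf-life state of one monitored product.

    ``SL_lo <= SL <= SL_hi`` is the shelf-life interval implied by the
    temperature-sensor accuracy.
    """

    t: float  # elapsed storage time (day)
    c: float  # current quality factor (N)
    k_current: float  # rate in effect (day⁻¹)
    SL: float  # predicted remaining shelf life (day)
    SL_lo: float = field(default=float("nan"))
    SL_hi: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"quality factor must be non-negative, got {self.c}")
        if self.SL < 0:
            raise ValueError(f"shelf life must be non-negative, got {self.SL}")
        lo = self.SL if math.isnan(self.SL_lo) else self.SL_lo
        hi = self.SL if math.isnan(self.SL_hi) else self.SL_hi
        object.__setattr__(self, "SL_lo", lo)
        object.__setattr__(self, "SL_hi", hi)
        if not (self.SL_lo <= self.SL + 1e-12 and self.SL <= self.SL_hi + 1e-12):
            raise ValueError("shelf-life bounds must bracket SL")


def _to_kelvin(T_C: float) -> float:
    if not math.isfinite(T_C):
        raise ValueError(f"temperature must be finite, got {T_C}")
    if T_C <= ABSOLUTE_ZERO_C:
        raise ValueError(f"temperature below absolute zero: {T_C} °C")
    return T_C + KELVIN_OFFSET


def arrhenius_rate(params: KineticParams, T_C: float) -> float:
    """Rate constant (day⁻¹) at temperature ``T_C`` via the Arrhenius ratio form."""
    T_K = _to_kelvin(T_C)
    ea_j = params.Ea * 1000.0  # kJ/mol -> J/mol
    return params.k_ref * math.exp(-(ea_j / R_GAS) * (1.0 / T_K - 1.0 / params.T_ref_K))


def rate_bounds(
    params: KineticParams, T_C: float, acc: float
) -> tuple[float, float]:
    """Rate interval ``(k_minus, k_plus)`` implied by a ±``acc`` °C sensor.

    ``k_minus`` (the pessimistic, larger rate) is evaluated at ``T + acc``
    and ``k_plus`` (optimistic, smaller) at ``T - acc``, matching the
    SL⁻/SL⁺ naming convention: the pessimistic rate yields the lower
    shelf-life bound.
    """
    if acc < 0:
        raise ValueError(f"sensor accuracy must be non-negative, got {acc}")
    return arrhenius_rate(params, T_C + acc), arrhenius_rate(params, T_C - acc)


def _decay(c: float, c_eq: float, k: float, dt: float, form: str) -> float:
    if form == "exponential":
        return max(0.0, c * math.exp(-k * dt))
    if form == "equilibrium":
        return c_eq + (c - c_eq) * math.exp(-k * dt)
    raise ValueError(f"unknown decay form {form!r}; expected one of {_DECAY_FORMS}")


def decay_step(
    state: QualityState,
    params: KineticParams,
    k: float,
    dt: float,
    form: str = "exponential",
) -> QualityState:
    """Advance a quality state by ``dt`` days at constant rate ``k``.

    ``form='exponential'`` applies c' = c·e^(−k·dt); ``form='equilibrium'``
    applies c' = c_eq + (c − c_eq)·e^(−k·dt).  Quality never increases.
    """
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    if k < 0:
        raise ValueError(f"rate must be non-negative, got {k}")
    c_new = _decay(state.c, params.c_eq, k, dt, form)
    sl = shelf_life(c_new, params, k) if k > 0 else state.SL
    return QualityState(t=state.t + dt, c=c_new, k_current=k, SL=sl)


def shelf_life(c_prime: float, params: KineticParams, k: float) -> float:
    """Remaining shelf life (day): (1/k)·ln(c'/c_eq), clamped at 0."""
    if k <= 0:
        raise ValueError(f"rate must be positive, got {k}")
    if params.c_eq <= 0:
        raise ValueError(f"c_eq must be positive for shelf-life evaluation, got {params.c_eq}")
    if c_prime <= params.c_eq:
        return 0.0
    return (1.0 / k) * math.log(c_prime / params.c_eq)


def shelf_life_bounds(
    c_prime: float, params: KineticParams, T_C: float, acc: float
) -> tuple[float, float]:
    """Shelf-life interval ``(SL_lo, SL_hi)`` under a ±``acc`` °C sensor."""
    k_minus, k_plus = rate_bounds(params, T_C, acc)
    return shelf_life(c_prime, params, k_minus), shelf_life(c_prime, params, k_plus)


def quality_trajectory(
    params: KineticParams,
    t_days: np.ndarray,
    T_C: np.ndarray,
    form: str = "exponential",
) -> np.ndarray:
    """Integrate the decay along a time-varying temperature series.

    The rate is held piecewise constant over each sampling interval, using
    the temperature reading at the interval's start — matching a discrete
    monitoring loop with one reading per tick.  Returns quality values at
    the given times (first element = c0).
    """
    t = np.asarray(t_days, dtype=float)
    T = np.asarray(T_C, dtype=float)
    if t.size == 0 or t.shape != T.shape:
        raise ValueError("t_days and T_C must be equal-length, non-empty")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("t_days must be strictly increasing")
    c = np.empty_like(t)
    c[0] = params.c0
    for i in range(1, t.size):
        k = arrhenius_rate(params, float(T[i - 1]))
        c[i] = _decay(c[i - 1], params.c_eq, k, float(t[i] - t[i - 1]), form)
    return c


@dataclass(frozen=True)
class RateFit:
    """Least-squares rate estimate with its standard error (day⁻¹)."""

    k: float
    stderr: float


def fit_rate(t_days, c) -> RateFit:
    """Estimate the exponential decay rate from an observed (t, c) series.

    Linearises the exponential form: the slope of −ln(c/c₀) against t is k.
    Accepts two or more observations with strictly increasing times and
    positive quality values.
    """
    t = np.asarray(t_days, dtype=float)
    cv = np.asarray(c, dtype=float)
    if t.ndim != 1 or t.shape != cv.shape or t.size < 2:
        raise ValueError("need at least 2 paired (t, c) observations")
    if not np.all(np.diff(t) > 0):
        raise ValueError("observation times must be strictly increasing")
    if not np.all(cv > 0):
        raise ValueError("quality observations must be positive")
    y = -np.log(cv / cv[0])
    if t.size == 2:
        return RateFit(k=float((y[1] - y[0]) / (t[1] - t[0])), stderr=0.0)
    res = stats.linregress(t, y)
    return RateFit(k=float(res.slope), stderr=float(res.stderr))
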