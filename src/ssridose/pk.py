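"""One-compartment pharmacokinetic simulation.

The plasma compartment receives drug through a first-order absorption
depot and loses it either by first-order elimination (linear model) or
by saturable Michaelis-Menten elimination:

    dC/dt = ka * (D/V) * exp(-ka * (t - t_dose)) - Vm * C / (Km + C)

summed over all past doses.  Doses are in mg, the apparent volume of
distribution V in litres and concentrations in ng/ml, so a dose D
contributes D * 1000 / V ng/ml to the (concentration-scaled) depot.

The linear model is evaluated by analytic superposition of the
single-dose bi-exponential; the Michaelis-Menten model is integrated
with a stiff-capable adaptive ODE solver, tracking the depot as an
explicit state so multi-dose schedules reduce to impulse updates of the
depot between smooth segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .exceptions import (
    ConvergenceError,
    DegenerateKineticsError,
    HorizonError,
    ValidationError,
)

__all__ = [
    "LinearPKParams",
    "MMPKParams",
    "DoseEvent",
    "DoseSchedule",
    "ConcentrationProfile",
    "simulate",
    "simulate_linear",
    "simulate_mm",
    "single_dose_profile",
    "daily_mean",
    "daily_means",
    "single_dose_metrics",
    "steady_state_cave",
    "plateau_daily_mean",
]

#: mg dose divided by litres of distribution volume -> ng/ml
MG_PER_L_TO_NG_PER_ML = 1000.0

#: default output grid spacing, hours
DEFAULT_RESOLUTION = 0.1

#: relative tolerance for the Michaelis-Menten integrator
MM_RTOL = 1e-9
MM_ATOL = 1e-12


@dataclass(frozen=True)
class LinearPKParams:
    """First-order absorption / first-order elimination constants.

    volume            apparent volume of distribution V, litres
    absorption_rate   ka (the absorption constant), 1/h
    elimination_rate  ke, 1/h
    """

    volume: float
    absorption_rate: float
    elimination_rate: float

    def __post_init__(self):
        for name in ("volume", "absorption_rate", "elimination_rate"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        ka, ke = self.absorption_rate, self.elimination_rate
        if abs(ka - ke) <= 1e-12 * max(ka, ke):
            raise DegenerateKineticsError(
                "absorption and elimination rates coincide; the "
                "bi-exponential solution is degenerate"
            )


@dataclass(frozen=True)
class MMPKParams:
    """First-order absorption / Michaelis-Menten elimination constants.

    volume           apparent volume of distribution V, litres
    absorption_rate  ka (K01), 1/h
    vmax             maximum elimination rate Vm, ng/ml/h
    km               Michaelis constant Km, ng/ml
    """

    volume: float
    absorption_rate: float
    vmax: float
    km: float

    def __post_init__(self):
        for name in ("volume", "absorption_rate", "vmax", "km"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: `time` hours after treatment start, `amount` mg."""

    time: float
    amount: float

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError("dose time must be >= 0")
        if self.amount < 0:
            raise ValidationError("dose amount must be >= 0")


@dataclass(frozen=True)
class DoseSchedule:
    """An ordered sequence of dose events with a nominal dosing interval."""

    events: tuple[DoseEvent, ...]
    interval: float = 24.0

    def __post_init__(self):
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if self.interval not in (12.0, 24.0, 12, 24):
            raise ValidationError("dosing interval must be 12 or 24 h")
        times = [e.time for e in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("dose event times must be non-decreasing")

    @classmethod
    def once_daily(cls, amounts: Sequence[float] | float, days: int | None = None):
        """Daily doses at t = 0, 24, 48, ... (one amount per day, or a
        constant amount repeated for `days` days)."""
        if np.isscalar(amounts):
            if days is None:
                raise ValidationError("days required with a scalar amount")
            amounts = [float(amounts)] * days
        events = tuple(DoseEvent(24.0 * i, float(a)) for i, a in enumerate(amounts))
        return cls(events=events, interval=24.0)

    @classmethod
    def twice_daily(cls, amounts: Sequence[float] | float, days: int | None = None):
        """Equal doses at t = 0 and 12 h within each day; `amounts` is the
        per-administration (12-hourly) dose for each day."""
        if np.isscalar(amounts):
            if days is None:
                raise ValidationError("days required with a scalar amount")
            amounts = [float(amounts)] * days
        events = []
        for i, a in enumerate(amounts):
            events.append(DoseEvent(24.0 * i, float(a)))
            events.append(DoseEvent(24.0 * i + 12.0, float(a)))
        return cls(events=tuple(events), interval=12.0)

    @classmethod
    def single(cls, amount: float, time: float = 0.0):
        return cls(events=(DoseEvent(time, float(amount)),), interval=24.0)

    @classmethod
    def empty(cls, interval: float = 24.0):
        return cls(events=(), interval=interval)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Plasma concentration (ng/ml) on a strictly increasing time grid (h)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.ndim != 1 or times.shape != conc.shape:
            raise ValidationError("times and concentrations must be aligned 1-d arrays")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValidationError("time grid must be strictly increasing")
        if np.any(conc < -1e-9):
            raise ValidationError("concentrations must be non-negative")
        conc = np.where(conc < 0, 0.0, conc)  # clip integrator noise
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)

    @property
    def horizon(self) -> float:
        return float(self.times[-1])


def _time_grid(horizon: float, resolution: float) -> np.ndarray:
    if resolution <= 0 or resolution > 0.5:
        raise ValidationError("resolution must be in (0, 0.5] h")
    n = int(round(horizon / resolution))
    return np.linspace(0.0, n * resolution, n + 1)


def _check_schedule(schedule: DoseSchedule, horizon: float) -> None:
    if any(e.time > horizon for e in schedule.events):
        raise ValidationError("horizon does not cover all dose events")


def simulate_linear(
    params: LinearPKParams,
    schedule: DoseSchedule,
    horizon: float,
    resolution: float = DEFAULT_RESOLUTION,
) -> ConcentrationProfile:
    """Multi-dose concentration profile by analytic superposition of
    single-dose bi-exponential terms."""
    _check_schedule(schedule, horizon)
    times = _time_grid(horizon, resolution)
    conc = linear_concentration(params, schedule.events, times)
    return ConcentrationProfile(times=times, concentrations=conc)


def linear_concentration(
    params: LinearPKParams,
    events: Sequence[DoseEvent],
    times: np.ndarray,
) -> np.ndarray:
    """Closed-form superposition C(t) = sum_i (Di/V) ka/(ka-ke)
    (exp(-ke tau_i) - exp(-ka tau_i)), tau_i = t - t_i."""
    times = np.asarray(times, dtype=float)
    ka, ke, v = params.absorption_rate, params.elimination_rate, params.volume
    pref = ka / (ka - ke)
    conc = np.zeros_like(times)
    for ev in events:
        if ev.amount == 0:
            continue
        tau = times - ev.time
        m = tau >= 0
        dv = ev.amount * MG_PER_L_TO_NG_PER_ML / v
        conc[m] += dv * pref * (np.exp(-ke * tau[m]) - np.exp(-ka * tau[m]))
    return conc


# ---------------------------------------------------------------------------
# Michaelis-Menten integration


def _mm_rhs(params: MMPKParams):
    ka, vm, km = params.absorption_rate, params.vmax, params.km

    def rhs(t, y):
        depot, conc = y
        return (-ka * depot, ka * depot - vm * conc / (km + conc))

    return rhs


def mm_integrate(
    params: MMPKParams,
    events: Sequence[DoseEvent],
    times: np.ndarray,
    state: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, tuple[float, float]]:
    """Integrate the Michaelis-Menten model over `times` (which must be
    strictly increasing and start at the current time), applying dose
    impulses to the depot state.  Returns concentrations on the grid and
    the final (depot, concentration) state.

    Doses at exactly `times[-1]` are applied to the returned state but do
    not affect the grid values, so consecutive segments chain exactly.
    """
    times = np.asarray(times, dtype=float)
    t0, t1 = float(times[0]), float(times[-1])
    depot, conc0 = state
    # merge simultaneous doses; impulses sorted by time
    impulses: dict[float, float] = {}
    for ev in events:
        if ev.time < t0 - 1e-9 or ev.time > t1 + 1e-9:
            raise ValidationError("dose event outside integration window")
        impulses[float(ev.time)] = impulses.get(float(ev.time), 0.0) + (
            ev.amount * MG_PER_L_TO_NG_PER_ML / params.volume
        )
    out = np.empty_like(times)
    rhs = _mm_rhs(params)
    bounds = sorted(t for t in impulses if t0 < t < t1)
    seg_edges = [t0] + bounds + [t1]
    if t0 in impulses:
        depot += impulses[t0]
    wrote = np.zeros(times.shape, dtype=bool)
    y = np.array([depot, conc0], dtype=float)
    for a, b in zip(seg_edges, seg_edges[1:]):
        m = (times >= a - 1e-12) & (times <= b + 1e-12) & ~wrote
        t_eval = times[m]
        if t_eval.size == 0 or t_eval[-1] < b - 1e-12:
            t_eval = np.append(t_eval, b)
            appended = True
        else:
            appended = False
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            t_eval=t_eval,
            method="LSODA",
            rtol=MM_RTOL,
            atol=MM_ATOL,
        )
        if not sol.success:  # pragma: no cover - LSODA is robust here
            raise ConvergenceError(f"ODE integration failed: {sol.message}")
        vals = sol.y[:, : t_eval.size - 1] if appended else sol.y
        if m.any():
            out[m] = np.maximum(vals[1], 0.0)
            wrote[m] = True
        y = sol.y[:, -1].copy()
        if b in impulses and b < t1:
            y[0] += impulses[b]
    if t1 in impulses:
        y[0] += impulses[t1]
    if times.size == 1:
        out[0] = conc0
    return out, (float(y[0]), float(max(y[1], 0.0)))


def simulate_mm(
    params: MMPKParams,
    schedule: DoseSchedule,
    horizon: float,
    resolution: float = DEFAULT_RESOLUTION,
) -> ConcentrationProfile:
    """Multi-dose concentration profile under Michaelis-Menten elimination.

    Absorption inputs superpose in the depot; the saturable elimination
    acts on the total concentration.
    """
    _check_schedule(schedule, horizon)
    times = _time_grid(horizon, resolution)
    if not schedule.events:
        return ConcentrationProfile(times=times, concentrations=np.zeros_like(times))
    conc, _ = mm_integrate(params, schedule.events, times)
    return ConcentrationProfile(times=times, concentrations=conc)


def simulate(params, schedule, horizon, resolution=DEFAULT_RESOLUTION):
    """Dispatch to the linear or Michaelis-Menten simulator by parameter type."""
    if isinstance(params, LinearPKParams):
        return simulate_linear(params, schedule, horizon, resolution)
    if isinstance(params, MMPKParams):
        return simulate_mm(params, schedule, horizon, resolution)
    raise ValidationError(f"unsupported parameter type: {type(params)!r}")


# ---------------------------------------------------------------------------
# Summary metrics


def daily_mean(profile: ConcentrationProfile, day_index: int) -> float:
    """Trapezoidal mean concentration over the 24 h window of 1-based
    `day_index` (hours [24*(day-1), 24*day])."""
    if day_index < 1:
        raise ValidationError("day_index is 1-based")
    lo, hi = 24.0 * (day_index - 1), 24.0 * day_index
    t, c = profile.times, profile.concentrations
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise HorizonError(f"profile does not cover day {day_index}")
    inner = (t > lo) & (t < hi)
    ts = np.concatenate(([lo], t[inner], [hi]))
    cs = np.concatenate(
        ([np.interp(lo, t, c)], c[inner], [np.interp(hi, t, c)])
    )
    return float(np.trapezoid(cs, ts) / 24.0)


def daily_means(profile: ConcentrationProfile, days: int) -> np.ndarray:
    return np.array([daily_mean(profile, d) for d in range(1, days + 1)])


#: tail window for the terminal half-life regression, as fractions of Cmax
_TAIL_FLOOR_FRAC = 1e-7
_TAIL_CEILING_FRAC = 1.0 / 8.0


def _refine_peak(t: np.ndarray, c: np.ndarray, i: int) -> tuple[float, float]:
    """Refine the grid maximum with a local cubic-spline fit."""
    lo, hi = max(i - 4, 0), min(i + 5, len(t))
    if i == 0 or i == len(t) - 1 or hi - lo < 4:
        return float(c[i]), float(t[i])
    spl = CubicSpline(t[lo:hi], c[lo:hi])
    crit = spl.derivative().roots(extrapolate=False)
    cand_t = np.concatenate((crit, [t[i]]))
    cand_c = spl(cand_t)
    j = int(np.argmax(cand_c))
    if cand_c[j] >= c[i]:
        return float(cand_c[j]), float(cand_t[j])
    return float(c[i]), float(t[i])


def single_dose_metrics(profile: ConcentrationProfile) -> tuple[float, float, float]:
    """(Cmax ng/ml, Tmax h, terminal t1/2 h) from a single-dose profile.

    Cmax/Tmax come from the grid maximum refined by local spline
    interpolation.  The half-life is the terminal (lambda_z-style)
    half-life: ln(2) divided by the slope of a log-linear regression over
    the deepest available decade of the post-peak tail (capped above at
    Cmax/8 so absorption no longer contaminates the slope).  For
    Michaelis-Menten kinetics this is the low-concentration apparent
    half-life ~ ln(2)*(Km+C)/Vm.
    """
    t, c = profile.times, profile.concentrations
    if t.size < 8:
        raise HorizonError("profile too short for single-dose metrics")
    i = int(np.argmax(c))
    cmax, tmax = _refine_peak(t, c, i)
    if cmax <= 0:
        raise ValidationError("profile is identically zero")
    tail = slice(i + 1, None)
    ct, tt = c[tail], t[tail]
    pos = ct > 0
    ct, tt = ct[pos], tt[pos]
    if ct.size < 5 or ct.min() > cmax / 2.0:
        raise HorizonError(
            "concentration never falls to Cmax/2 within the horizon; "
            "extend the simulation"
        )
    lo = max(float(ct.min()), cmax * _TAIL_FLOOR_FRAC)
    hi = min(lo * 10.0, cmax * _TAIL_CEILING_FRAC)
    m = (ct >= lo) & (ct <= hi)
    if m.sum() < 5:  # thin tail: widen toward Cmax/4
        hi = min(lo * 10.0, cmax / 4.0)
        m = (ct >= lo) & (ct <= hi)
    if m.sum() < 5:
        raise HorizonError(
            "too few tail points below Cmax/8 to estimate the terminal "
            "half-life; extend the simulation horizon"
        )
    slope = np.polyfit(tt[m], np.log(ct[m]), 1)[0]
    if slope >= 0:
        raise HorizonError("non-decaying tail; cannot estimate half-life")
    t_half = math.log(2.0) / (-slope)
    return float(cmax), float(tmax), float(t_half)


def _single_dose_horizon(params, dose: float) -> float:
    """Horizon long enough for the terminal-tail regression window."""
    if isinstance(params, LinearPKParams):
        ka, ke = params.absorption_rate, params.elimination_rate
        tmax = math.log(ka / ke) / (ka - ke)
        # decay to ~1e-8 of Cmax so the deepest decade is clean
        return tmax + math.log(1e8) / ke
    # MM: zero-order phase cmax/vm plus first-order tail at ke ~ Vm/Km
    ke_term = params.vmax / params.km
    cmax_scale = dose * MG_PER_L_TO_NG_PER_ML / params.volume
    return (
        5.0 / params.absorption_rate
        + cmax_scale / params.vmax
        + math.log(1e4) / ke_term
    )


def single_dose_profile(
    params,
    dose: float,
    resolution: float = DEFAULT_RESOLUTION,
    horizon: float | None = None,
) -> ConcentrationProfile:
    """Simulate one dose at t=0 with a horizon long enough for
    `single_dose_metrics` (deep terminal tail)."""
    if horizon is None:
        horizon = _single_dose_horizon(params, dose)
    return simulate(params, DoseSchedule.single(dose), horizon, resolution)


# ---------------------------------------------------------------------------
# Steady state


def _regimen_schedule(dose: float, interval: float, days: int) -> DoseSchedule:
    if interval == 24:
        return DoseSchedule.once_daily(dose, days)
    return DoseSchedule.twice_daily(dose, days)


def regimen_daily_means(
    params,
    dose: float,
    interval: float,
    days: int,
    resolution: float = DEFAULT_RESOLUTION,
) -> np.ndarray:
    """Daily mean concentrations for a constant regimen of `dose` mg per
    administration every `interval` hours, over `days` days."""
    schedule = _regimen_schedule(dose, interval, days)
    profile = simulate(params, schedule, 24.0 * days, resolution)
    return daily_means(profile, days)


def steady_state_cave(
    params,
    dose: float,
    interval: float = 24.0,
    tolerance: float = 1e-3,
    max_days: int = 60,
    resolution: float = DEFAULT_RESOLUTION,
) -> tuple[float, int]:
    """Steady-state daily mean under a constant regimen.

    Returns (css, day_reached): the daily mean on the first day whose
    relative change from the previous day falls below `tolerance`.
    Raises ConvergenceError (carrying the last daily mean) if the cap of
    `max_days` days is hit first.
    """
    if not 0 < tolerance <= 0.05:
        raise ValidationError("tolerance must be in (0, 0.05]")
    if dose == 0:
        return 0.0, 1
    means = regimen_daily_means(params, dose, interval, max_days, resolution)
    for d in range(1, max_days):
        prev, cur = means[d - 1], means[d]
        if cur == 0 and prev == 0:
            return 0.0, d + 1
        if abs(cur - prev) / max(cur, prev) < tolerance:
            return float(cur), d + 1
    raise ConvergenceError(
        f"daily mean not converged within {max_days} days",
        last_value=float(means[-1]),
    )


def plateau_daily_mean(
    params,
    dose: float,
    interval: float = 24.0,
    settle_days: int = 60,
    resolution: float = DEFAULT_RESOLUTION,
) -> float:
    """Daily mean on day `settle_days` of a constant regimen: the
    steady-state anchor used by the titration stage."""
    if dose == 0:
        return 0.0
    return float(
        regimen_daily_means(params, dose, interval, settle_days, resolution)[-1]
    )
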