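"""Fluoxetine-matched escalating dose regimens.

Fluoxetine's slow accumulation under a standard 40 mg/day regimen is the
safety reference: its daily mean concentration, expressed as a fraction
of the steady-state mean, defines a 30-day loading curve.  For any other
drug the titration stage scales those fractions by the drug's own
steady-state mean (simulated under its standard maintenance regimen) to
obtain daily concentration targets, then solves each day's dose by
root-finding on the simulator, conditioning on all previously fixed
doses.  Because the daily mean is strictly increasing in that day's
dose, the root is unique.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import pk
from .exceptions import InfeasibleDoseError, ValidationError

__all__ = [
    "ReferenceProfile",
    "TitrationResult",
    "build_reference",
    "daily_targets",
    "solve_daily_dose",
    "generate_titration",
]

#: relative tolerance on the achieved daily mean
SOLVER_REL_TOL = 1e-3

#: days simulated to anchor a steady-state mean
SETTLE_DAYS = 60


@dataclass(frozen=True)
class ReferenceProfile:
    """The loading curve of the reference drug (fluoxetine).

    daily_means  daily mean concentrations, ng/ml
    css          steady-state mean concentration, ng/ml
    fractions    daily_means / css, the titration target fractions
    """

    daily_means: np.ndarray
    css: float
    fractions: np.ndarray

    def __post_init__(self):
        dm = np.asarray(self.daily_means, dtype=float)
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "daily_means", dm)
        object.__setattr__(self, "fractions", fr)
        if not self.css > 0:
            raise ValidationError("css must be strictly positive")
        if np.any(fr <= 0) or np.any(fr > 1.001):
            raise ValidationError("fractions must lie in (0, 1.001]")
        if np.any(np.diff(fr) < 0):
            raise ValidationError("fractions must be non-decreasing")

    @property
    def days(self) -> int:
        return len(self.daily_means)


@dataclass(frozen=True)
class TitrationResult:
    """Solved escalating regimen for one drug.

    doses                 per-administration dose for each day, mg
    achieved_daily_means  daily means re-simulated from the solved doses
    targets               the daily concentration targets, ng/ml
    interval              dosing interval, h (24, or 12 with two equal
                          doses per day)
    """

    doses: np.ndarray
    achieved_daily_means: np.ndarray
    targets: np.ndarray
    interval: float = 24.0

    def __post_init__(self):
        for name in ("doses", "achieved_daily_means", "targets"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        if np.any(self.doses < 0):
            raise ValidationError("doses must be non-negative")

    def schedule(self) -> pk.DoseSchedule:
        if self.interval == 24:
            return pk.DoseSchedule.once_daily(self.doses)
        return pk.DoseSchedule.twice_daily(self.doses)


def build_reference(
    params_reference,
    dose: float = 40.0,
    days: int = 30,
    interval: float = 24.0,
    settle_days: int = SETTLE_DAYS,
    resolution: float = pk.DEFAULT_RESOLUTION,
) -> ReferenceProfile:
    """Simulate the reference drug's standard regimen and extract the
    loading fractions.

    The steady-state mean is taken as the daily mean after `settle_days`
    days (long past convergence for every drug considered), so the
    day-30 fraction sits just below 1 rather than marginally above it.
    """
    if days < 1:
        raise ValidationError("days must be >= 1")
    horizon_days = max(days, settle_days)
    means = pk.regimen_daily_means(
        params_reference, dose, interval, horizon_days, resolution
    )
    css = float(means[-1])
    daily = means[:days]
    return ReferenceProfile(daily_means=daily, css=css, fractions=daily / css)


def daily_targets(reference: ReferenceProfile, drug_css: float) -> np.ndarray:
    """Per-day concentration targets: fraction_i * drug_css."""
    if not drug_css > 0:
        raise ValidationError("drug_css must be strictly positive")
    return reference.fractions * drug_css


class _DayMeanEvaluator:
    """Evaluates (and commits) one day's mean given the fixed history.

    For the linear model the day window is evaluated by analytic
    superposition; for the Michaelis-Menten model the integrator state
    (depot, concentration) at the day boundary is cached so each
    candidate dose costs a single 24 h integration.
    """

    def __init__(self, params, interval: float, resolution: float):
        self.params = params
        self.interval = float(interval)
        self.resolution = resolution
        self.is_mm = isinstance(params, pk.MMPKParams)
        self.history: list[pk.DoseEvent] = []
        self._state = (0.0, 0.0)  # MM (depot, conc) at t = 24*(day-1)
        self._day = 1  # next day to be solved (1-based)

    def _day_events(self, dose: float) -> list[pk.DoseEvent]:
        t0 = 24.0 * (self._day - 1)
        if self.interval == 24:
            return [pk.DoseEvent(t0, dose)]
        return [pk.DoseEvent(t0, dose), pk.DoseEvent(t0 + 12.0, dose)]

    def _window_grid(self) -> np.ndarray:
        t0 = 24.0 * (self._day - 1)
        n = int(round(24.0 / self.resolution))
        return t0 + np.linspace(0.0, 24.0, n + 1)

    def day_mean(self, dose: float) -> float:
        grid = self._window_grid()
        events = self._day_events(dose)
        if self.is_mm:
            conc, _ = pk.mm_integrate(self.params, events, grid, self._state)
        else:
            conc = pk.linear_concentration(
                self.params, self.history + events, grid
            )
        return float(np.trapezoid(conc, grid) / 24.0)

    def commit(self, dose: float) -> None:
        events = self._day_events(dose)
        if self.is_mm:
            grid = self._window_grid()
            _, self._state = pk.mm_integrate(self.params, events, grid, self._state)
        self.history.extend(events)
        self._day += 1

    def advance_history(self, events: list[pk.DoseEvent], day: int) -> None:
        """Fast-forward to the start of 1-based `day`, conditioning on
        pre-existing dose events (all strictly before that day)."""
        t_end = 24.0 * (day - 1)
        if any(e.time >= t_end for e in events):
            raise ValidationError("fixed history must precede the solved day")
        if self.is_mm and t_end > 0:
            n = int(round(t_end / self.resolution))
            grid = np.linspace(0.0, t_end, n + 1)
            _, self._state = pk.mm_integrate(self.params, events, grid)
        self.history = list(events)
        self._day = day


def _solve_day(
    evaluator: _DayMeanEvaluator,
    target: float,
    upper: float,
    day: int,
    rel_tol: float = SOLVER_REL_TOL,
) -> float:
    if target <= 0:
        raise ValidationError("target must be strictly positive")
    baseline = evaluator.day_mean(0.0)
    if baseline >= target:
        # carry-over from earlier doses already exceeds the target
        if (baseline - target) / target <= rel_tol:
            return 0.0
        raise InfeasibleDoseError(
            f"day {day}: residual concentration ({baseline:.3g}) already "
            f"exceeds the target ({target:.3g})",
            day=day,
        )
    top = evaluator.day_mean(upper)
    if top < target:
        raise InfeasibleDoseError(
            f"day {day}: target {target:.3g} ng/ml unreachable with doses "
            f"up to {upper:g} mg",
            day=day,
        )
    dose = brentq(
        lambda d: evaluator.day_mean(d) - target,
        0.0,
        upper,
        xtol=1e-9 * max(upper, 1.0),
        rtol=1e-7,
    )
    achieved = evaluator.day_mean(dose)
    if abs(achieved - target) / target > rel_tol:  # pragma: no cover
        raise InfeasibleDoseError(
            f"day {day}: solver left a residual of "
            f"{abs(achieved - target) / target:.2%}",
            day=day,
        )
    return float(dose)


def solve_daily_dose(
    params,
    fixed_history: pk.DoseSchedule,
    day: int,
    target: float,
    bounds: tuple[float, float] | float = 10000.0,
    resolution: float = pk.DEFAULT_RESOLUTION,
) -> float:
    """Per-administration dose for 1-based `day` such that the simulated
    daily mean equals `target` within 0.1% relative, by bisection-style
    bracketed root-finding (the daily mean is strictly increasing in the
    dose, so the root is unique).  With a 12 h interval the two doses of
    the day are constrained equal."""
    upper = bounds[1] if isinstance(bounds, (tuple, list)) else float(bounds)
    evaluator = _DayMeanEvaluator(params, fixed_history.interval, resolution)
    evaluator.advance_history(list(fixed_history.events), day)
    return _solve_day(evaluator, target, upper, day)


def generate_titration(
    params,
    standard_dose: float,
    interval: float,
    reference: ReferenceProfile,
    rounding: float | None = None,
    resolution: float = pk.DEFAULT_RESOLUTION,
    drug_css: float | None = None,
    bounds_factor: float = 10.0,
) -> TitrationResult:
    """Solve the full escalating regimen for one drug.

    The drug's steady-state anchor is the daily mean after 60 days of its
    standard maintenance regimen (`standard_dose` every `interval` h),
    overridable via `drug_css`.  Days are solved sequentially; each day's
    solve conditions on the previously fixed (optionally rounded) doses.
    Achieved daily means are reported from one final re-simulation of the
    complete solved schedule.
    """
    if drug_css is None:
        drug_css = pk.plateau_daily_mean(
            params, standard_dose, interval, resolution=resolution
        )
    targets = daily_targets(reference, drug_css)
    upper = bounds_factor * standard_dose
    evaluator = _DayMeanEvaluator(params, interval, resolution)
    doses = []
    for day in range(1, reference.days + 1):
        dose = _solve_day(evaluator, targets[day - 1], upper, day)
        if rounding is not None and rounding > 0:
            dose = math.floor(dose / rounding + 0.5) * rounding
        doses.append(dose)
        evaluator.commit(dose)
    doses = np.array(doses)
    schedule = (
        pk.DoseSchedule.once_daily(doses)
        if interval == 24
        else pk.DoseSchedule.twice_daily(doses)
    )
    profile = pk.simulate(params, schedule, 24.0 * reference.days, resolution)
    achieved = pk.daily_means(profile, reference.days)
    return TitrationResult(
        doses=doses,
        achieved_daily_means=achieved,
        targets=targets,
        interval=interval,
    )
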