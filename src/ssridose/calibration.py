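"""Derive model parameters from published single-dose observables.

Linear drugs are specified in the literature by (V, t1/2, Tmax): the
elimination constant is ke = ln2 / t1/2 and the absorption constant is
the ka > ke solving the peak-time identity

    Tmax = ln(ka / ke) / (ka - ke).

Saturable (Michaelis-Menten) drugs are specified by a single-dose
(Cmax, Tmax, t1/2) triple at a reference dose.  Four parameters
(V, K01, Vm, Km) against three observables is underdetermined, so the
fit is a bounded least-squares in log-parameter space; supplying a Km
prior pins the free direction, otherwise the minimum-residual solution
is returned with a degeneracy warning.  Every calibration is verified by
forward simulation through the same metrics used everywhere else.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from . import pk
from .exceptions import CalibrationError, ValidationError

__all__ = [
    "ObservableTriple",
    "solve_absorption_rate",
    "calibrate_linear",
    "calibrate_mm",
    "forward_check",
]


@dataclass(frozen=True)
class ObservableTriple:
    """Published single-dose observables for one drug.

    cmax     peak concentration, ng/ml (None for linear drugs, whose
             volume is published instead)
    tmax     time of the peak, h
    t_half   terminal half-life, h
    ref_dose dose at which the observables were measured, mg
    volume   apparent volume of distribution, litres (linear drugs)
    """

    tmax: float
    t_half: float
    cmax: float | None = None
    ref_dose: float | None = None
    volume: float | None = None

    def __post_init__(self):
        for name in ("tmax", "t_half", "cmax", "ref_dose", "volume"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be strictly positive")


def solve_absorption_rate(ke: float, tmax: float) -> float:
    """The ka > ke solving Tmax = ln(ka/ke)/(ka - ke), by bracketed
    root-finding.  No solution exists once tmax >= 1/ke (the peak of a
    first-order absorption curve cannot occur later than 1/ke)."""
    if ke <= 0 or tmax <= 0:
        raise ValidationError("ke and tmax must be strictly positive")
    if tmax >= 1.0 / ke:
        raise CalibrationError(
            f"tmax={tmax:g} h >= 1/ke={1.0 / ke:g} h: no absorption rate "
            "faster than elimination can produce this peak time"
        )

    def f(ka):
        return math.log(ka / ke) / (ka - ke) - tmax

    lo = ke * (1.0 + 1e-9)
    hi = ke * 2.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > ke * 1e9:  # pragma: no cover
            raise CalibrationError("failed to bracket the absorption rate")
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=200))


def calibrate_linear(obs: ObservableTriple) -> pk.LinearPKParams:
    """(V, t1/2, Tmax) -> LinearPKParams with ke = ln2/t1/2 and ka from
    the peak-time identity."""
    if obs.volume is None:
        raise ValidationError("linear calibration requires a volume")
    ke = math.log(2.0) / obs.t_half
    ka = solve_absorption_rate(ke, obs.tmax)
    return pk.LinearPKParams(
        volume=obs.volume, absorption_rate=ka, elimination_rate=ke
    )


def _mm_initial_guess(obs: ObservableTriple, km0: float) -> pk.MMPKParams:
    """Linearized starting point: treat the drug as first-order with
    ke = ln2/t1/2, then Vm = ke*Km and V from the peak height."""
    ke = math.log(2.0) / obs.t_half
    ka = solve_absorption_rate(ke, obs.tmax)
    peak = (
        ka / (ka - ke) * (math.exp(-ke * obs.tmax) - math.exp(-ka * obs.tmax))
    )
    volume = obs.ref_dose * pk.MG_PER_L_TO_NG_PER_ML * peak / obs.cmax
    return pk.MMPKParams(volume=volume, absorption_rate=ka, vmax=ke * km0, km=km0)


def _mm_residuals(params: pk.MMPKParams, obs: ObservableTriple, resolution: float):
    profile = pk.single_dose_profile(params, obs.ref_dose, resolution)
    cmax, tmax, t_half = pk.single_dose_metrics(profile)
    return np.array(
        [
            (cmax - obs.cmax) / obs.cmax,
            (tmax - obs.tmax) / obs.tmax,
            (t_half - obs.t_half) / obs.t_half,
        ]
    )


def calibrate_mm(
    obs: ObservableTriple,
    km_prior: float | None = None,
    x0: pk.MMPKParams | None = None,
    resolution: float = pk.DEFAULT_RESOLUTION,
    tol: float = 0.01,
) -> pk.MMPKParams:
    """Fit (V, K01, Vm, Km) so a forward single-dose simulation at
    `ref_dose` reproduces (cmax, tmax, t_half) to within `tol` relative.

    With `km_prior`, Km is held fixed and the remaining three parameters
    are fitted (a well-posed 3x3 system).  Without it, Km is a free
    bounded parameter: the problem is underdetermined and the returned
    minimum-residual solution is one point on a one-parameter family
    (a degeneracy warning is issued).
    """
    if obs.cmax is None or obs.ref_dose is None:
        raise ValidationError("MM calibration requires cmax and ref_dose")
    km0 = km_prior if km_prior is not None else 10.0 * obs.cmax
    guess = x0 if x0 is not None else _mm_initial_guess(obs, km0)

    free_km = km_prior is None
    if free_km:
        theta0 = np.log([guess.volume, guess.absorption_rate, guess.vmax, guess.km])
        lo = np.log([1.0, 1e-3, 1e-4, max(1.0, obs.cmax * 0.5)])
        hi = np.log([1e5, 50.0, 1e4, 1e5])
    else:
        theta0 = np.log([guess.volume, guess.absorption_rate, guess.vmax])
        lo = np.log([1.0, 1e-3, 1e-4])
        hi = np.log([1e5, 50.0, 1e4])
    theta0 = np.clip(theta0, lo, hi)

    def unpack(theta):
        if free_km:
            v, ka, vm, km = np.exp(theta)
        else:
            v, ka, vm = np.exp(theta)
            km = km_prior
        return pk.MMPKParams(volume=v, absorption_rate=ka, vmax=vm, km=km)

    def fun(theta):
        return _mm_residuals(unpack(theta), obs, resolution)

    result = least_squares(
        fun, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=None
    )
    params = unpack(result.x)
    residuals = _mm_residuals(params, obs, resolution)
    if np.max(np.abs(residuals)) > tol:
        raise CalibrationError(
            "MM calibration failed: relative residuals "
            f"(cmax, tmax, t_half) = {residuals.round(4).tolist()} exceed "
            f"{tol:.1%}",
            residuals=residuals,
        )
    if free_km:
        warnings.warn(
            "Km was fitted without a prior: three observables cannot pin "
            "four parameters, so the returned set is one point on a "
            "degenerate family",
            stacklevel=2,
        )
    return params


def forward_check(
    params,
    ref_dose: float,
    obs: ObservableTriple,
    resolution: float = pk.DEFAULT_RESOLUTION,
) -> dict[str, float]:
    """Simulate one `ref_dose`, extract (Cmax, Tmax, t1/2) and report the
    relative residual against each published observable (keys with a
    None observable are omitted)."""
    profile = pk.single_dose_profile(params, ref_dose, resolution)
    cmax, tmax, t_half = pk.single_dose_metrics(profile)
    report: dict[str, float] = {}
    if obs.cmax is not None:
        report["cmax"] = (cmax - obs.cmax) / obs.cmax
    report["tmax"] = (tmax - obs.tmax) / obs.tmax
    report["t_half"] = (t_half - obs.t_half) / obs.t_half
    return report
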