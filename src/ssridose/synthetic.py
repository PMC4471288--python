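"""Synthetic inputs for end-to-end testing without external data.

Two generators cover the pipeline's inputs:

* random one-compartment drugs (linear or Michaelis-Menten) in
  physiological ranges, together with the single-dose observables a
  pharmacology paper would print for them.  Observables are measured by
  forward simulation through the same metrics the calibration stage
  uses, never computed from the parameters analytically, so calibration
  round-trips are honest end-to-end exercises;

* bivariate (ln t1/2, RR) records with a controlled true correlation for
  the SRE analysis.

All generators are pure functions of their seed; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pk
from .calibration import ObservableTriple, solve_absorption_rate
from .correlation import DrugSRERecord
from .exceptions import ValidationError

__all__ = ["SyntheticDrugSpec", "gen_pk_drug", "gen_sre_records"]

#: grid spacing for measuring synthetic observables, h
OBSERVABLE_RESOLUTION = 0.05


@dataclass(frozen=True)
class SyntheticDrugSpec:
    """Sampling ranges for a random drug.  Defaults bracket the published
    SSRI values (volumes of a few hundred to ~2000 l, half-lives of a few
    hours to 2.5 days, peaks within the first dosing interval).

    Peak times are additionally capped at half the elimination time
    constant (tmax <= 0.5/ke): beyond ~1/ke no absorption rate can
    produce the peak, and near it absorption and elimination rates become
    practically indistinguishable (flip-flop kinetics), which no
    published SSRI exhibits.
    """

    seed: int
    model: str = "linear"  # "linear" | "mm"
    v_range: tuple[float, float] = (100.0, 2000.0)
    t_half_range: tuple[float, float] = (5.0, 60.0)
    tmax_range: tuple[float, float] = (2.0, 10.0)
    km_range: tuple[float, float] = (50.0, 1000.0)
    dose_range: tuple[float, float] = (20.0, 80.0)

    def __post_init__(self):
        if self.model not in ("linear", "mm"):
            raise ValidationError("model must be 'linear' or 'mm'")
        for name in ("v_range", "t_half_range", "tmax_range", "km_range", "dose_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 < low <= high")


def _draw(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def gen_pk_drug(spec: SyntheticDrugSpec):
    """Draw one random drug.

    Returns (params, observables): the generating parameter set and the
    ObservableTriple measured from a forward single-dose simulation.
    """
    rng = np.random.default_rng(spec.seed)
    volume = _draw(rng, *spec.v_range)
    t_half = _draw(rng, *spec.t_half_range)
    ke = np.log(2.0) / t_half
    tmax_hi = min(spec.tmax_range[1], 0.5 / ke)
    tmax_lo = min(spec.tmax_range[0], tmax_hi)
    tmax = _draw(rng, tmax_lo, tmax_hi)
    dose = _draw(rng, *spec.dose_range)

    if spec.model == "linear":
        ka = solve_absorption_rate(ke, tmax)
        params = pk.LinearPKParams(
            volume=volume, absorption_rate=ka, elimination_rate=ke
        )
    else:
        km = _draw(rng, *spec.km_range)
        vmax = ke * km  # terminal half-life of the drawn t_half
        ka = solve_absorption_rate(ke, tmax)
        params = pk.MMPKParams(
            volume=volume, absorption_rate=ka, vmax=vmax, km=km
        )

    profile = pk.single_dose_profile(params, dose, OBSERVABLE_RESOLUTION)
    cmax, tmax_obs, t_half_obs = pk.single_dose_metrics(profile)
    observables = ObservableTriple(
        cmax=cmax,
        tmax=tmax_obs,
        t_half=t_half_obs,
        ref_dose=dose,
        volume=volume,
    )
    return params, observables


def gen_sre_records(
    n: int,
    true_r: float,
    seed: int,
    population: str = "adult",
    ln_t_half_mean: float = np.log(30.0),
    ln_t_half_sd: float = 0.6,
    rr_mean: float = 2.0,
    rr_sd: float = 1.0,
) -> list[DrugSRERecord]:
    """Records whose (ln t1/2, RR) pairs follow a bivariate normal with
    correlation `true_r`; half-lives are exponentiated back to hours.

    Relative risks are floored at 0.05 to respect positivity; with the
    default location/scale the floor binds with probability ~2e-2 % per
    draw and does not visibly distort the correlation.
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    if abs(true_r) > 1:
        raise ValidationError("|true_r| must be <= 1")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = ln_t_half_mean + ln_t_half_sd * z1
    y_std = true_r * z1 + np.sqrt(max(0.0, 1.0 - true_r**2)) * z2
    y = np.maximum(rr_mean + rr_sd * y_std, 0.05)
    return [
        DrugSRERecord(
            drug=f"synthetic-{i + 1:02d}",
            population=population,
            t_half=float(np.exp(x[i])),
            rr_sre=float(y[i]),
            citation="synthetic",
        )
        for i in range(n)
    ]
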