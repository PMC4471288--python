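"""Bundled constants: published per-drug assumptions, the published
30-day dose schedules, and the illustrative half-life/SRE fixture.

Fluoxetine ships with its published Michaelis-Menten constants
(V = 1033 l, K01 = 0.53 /h, Vm = 6.5 ng/ml/h, Km = 448 ng/ml) used
verbatim; the linear drugs (sertraline, citalopram, venlafaxine) are
calibrated from their published (V, t1/2, Tmax); paroxetine and
fluvoxamine, whose constants were never published, are calibrated from
their single-dose (Cmax, Tmax, t1/2) observables.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import pk
from .calibration import ObservableTriple, calibrate_linear, calibrate_mm
from .correlation import DrugSRERecord
from .exceptions import ValidationError

__all__ = [
    "load_published_assumptions",
    "load_published_schedules",
    "published_schedule",
    "load_sre_fixture",
    "fluoxetine_params",
    "fluoxetine_observables",
    "DrugSpec",
    "build_drug_registry",
    "TITRATED_DRUGS",
    "REFERENCE_DRUG",
    "REFERENCE_DOSE_MG",
]

REFERENCE_DRUG = "fluoxetine"
REFERENCE_DOSE_MG = 40.0
TITRATED_DRUGS = ("paroxetine", "citalopram", "sertraline", "venlafaxine", "fluvoxamine")


def _data_path(name: str):
    return resources.files("ssridose.data").joinpath(name)


@functools.lru_cache(maxsize=None)
def load_published_assumptions() -> pd.DataFrame:
    """Per-drug published assumptions with a citation column."""
    with resources.as_file(_data_path("published_assumptions.csv")) as p:
        return pd.read_csv(p)


@functools.lru_cache(maxsize=None)
def load_published_schedules() -> pd.DataFrame:
    """The published 30-day dose columns (per-administration mg; the
    fluvoxamine column is a 12-hourly dose, all others are daily)."""
    with resources.as_file(_data_path("published_schedules.csv")) as p:
        return pd.read_csv(p)


def published_schedule(drug: str) -> pk.DoseSchedule:
    """The published 30-day escalating schedule for `drug` as a
    DoseSchedule (two equal 12-hourly doses per day for fluvoxamine)."""
    df = load_published_schedules()
    sub = df[df["drug"] == drug].sort_values("day")
    if sub.empty:
        raise ValidationError(f"no published schedule for {drug!r}")
    doses = sub["dose_mg"].to_numpy(dtype=float)
    interval = float(
        load_published_assumptions().set_index("drug").loc[drug, "interval_h"]
    )
    if interval == 12:
        return pk.DoseSchedule.twice_daily(doses)
    return pk.DoseSchedule.once_daily(doses)


def load_sre_fixture() -> list[DrugSRERecord]:
    """The bundled half-life/relative-risk records.

    This is a synthetic, illustrative stand-in: the underlying drug-level
    values were never published alongside the dosing analysis, so these
    rows were assembled from public PK half-lives and the 2004 FDA
    pediatric meta-analysis risk ratios.  Treat them as editable example
    data, not ground truth.
    """
    with resources.as_file(_data_path("sre_records_synthetic.csv")) as p:
        df = pd.read_csv(p)
    return [
        DrugSRERecord(
            drug=row.drug,
            population=row.population,
            t_half=float(row.t_half_h),
            rr_sre=float(row.rr_sre),
            citation=str(row.citation),
        )
        for row in df.itertuples()
    ]


def fluoxetine_params() -> pk.MMPKParams:
    """The published fluoxetine Michaelis-Menten constants, verbatim."""
    row = load_published_assumptions().set_index("drug").loc["fluoxetine"]
    return pk.MMPKParams(
        volume=float(row.volume_l),
        absorption_rate=float(row.ka_per_h),
        vmax=float(row.vm_ng_ml_h),
        km=float(row.km_ng_ml),
    )


def fluoxetine_observables() -> ObservableTriple:
    """The published single-dose fluoxetine observables
    (Cmax 35 ng/ml, Tmax 7 h, t1/2 48 h after one 40 mg dose)."""
    row = load_published_assumptions().set_index("drug").loc["fluoxetine"]
    return ObservableTriple(
        cmax=float(row.cmax_ng_ml),
        tmax=float(row.tmax_h),
        t_half=float(row.t_half_h),
        ref_dose=float(row.ref_dose_mg),
        volume=float(row.volume_l),
    )


@dataclass(frozen=True)
class DrugSpec:
    """A ready-to-simulate drug: calibrated parameters plus its dosing
    interval and standard maintenance dose (the steady-state anchor)."""

    name: str
    model: str  # "linear" | "mm"
    params: object
    interval: float
    standard_dose: float


def _spec_from_row(row) -> DrugSpec:
    model = row.model
    if model == "mm":
        params = pk.MMPKParams(
            volume=float(row.volume_l),
            absorption_rate=float(row.ka_per_h),
            vmax=float(row.vm_ng_ml_h),
            km=float(row.km_ng_ml),
        )
        kind = "mm"
    elif model == "linear":
        params = calibrate_linear(
            ObservableTriple(
                volume=float(row.volume_l),
                t_half=float(row.t_half_h),
                tmax=float(row.tmax_h),
            )
        )
        kind = "linear"
    elif model == "mm_observables":
        obs = ObservableTriple(
            cmax=float(row.cmax_ng_ml),
            tmax=float(row.tmax_h),
            t_half=float(row.t_half_h),
            ref_dose=float(row.ref_dose_mg),
        )
        with warnings.catch_warnings():
            # Km is deliberately left free for these drugs; the
            # degeneracy is documented, no need to warn on every build
            warnings.simplefilter("ignore")
            params = calibrate_mm(obs)
        kind = "mm"
    else:
        raise ValidationError(f"unknown model {model!r} for drug {row.drug!r}")
    return DrugSpec(
        name=row.drug,
        model=kind,
        params=params,
        interval=float(row.interval_h),
        standard_dose=float(row.standard_dose_mg),
    )


@functools.lru_cache(maxsize=None)
def _default_registry() -> dict[str, DrugSpec]:
    df = load_published_assumptions()
    return {row.drug: _spec_from_row(row) for row in df.itertuples()}


def build_drug_registry(assumptions: pd.DataFrame | None = None) -> dict[str, DrugSpec]:
    """Calibrate every configured drug and return name -> DrugSpec.

    Without an explicit assumptions table the bundled published values
    are used (and the result is cached, since the two saturable drugs
    require an optimisation each).
    """
    if assumptions is None:
        return dict(_default_registry())
    return {row.drug: _spec_from_row(row) for row in assumptions.itertuples()}
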