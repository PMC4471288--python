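"""CSV and YAML interfaces.

All tabular I/O is plain CSV with a header row:

* drug parameter files: drug, model, volume_l, ka_per_h, ke_per_h,
  vm_ng_ml_h, km_ng_ml, interval_h (empty cells where not applicable);
* schedule files: drug, day, dose_mg (per administration);
* profiles: time_h, conc_ng_ml;
* SRE records: drug, population, t_half_h, rr_sre, citation.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import pk
from .correlation import DrugSRERecord
from .exceptions import ValidationError

__all__ = [
    "read_drug_params_csv",
    "write_drug_params_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "read_profile_csv",
    "write_profile_csv",
    "read_sre_csv",
    "write_sre_csv",
    "load_config",
]

PARAM_COLUMNS = [
    "drug", "model", "volume_l", "ka_per_h", "ke_per_h",
    "vm_ng_ml_h", "km_ng_ml", "interval_h",
]


def write_drug_params_csv(path, specs: Mapping[str, tuple[object, float]]) -> None:
    """Write {drug: (params, interval_h)} to the parameter CSV dialect."""
    rows = []
    for drug, (params, interval) in specs.items():
        row = {c: "" for c in PARAM_COLUMNS}
        # repr() keeps full double precision so files round-trip losslessly
        row.update(drug=drug, interval_h=repr(float(interval)),
                   volume_l=repr(float(params.volume)),
                   ka_per_h=repr(float(params.absorption_rate)))
        if isinstance(params, pk.LinearPKParams):
            row.update(model="linear",
                       ke_per_h=repr(float(params.elimination_rate)))
        elif isinstance(params, pk.MMPKParams):
            row.update(model="mm", vm_ng_ml_h=repr(float(params.vmax)),
                       km_ng_ml=repr(float(params.km)))
        else:
            raise ValidationError(f"unsupported params for {drug!r}")
        rows.append(row)
    pd.DataFrame(rows, columns=PARAM_COLUMNS).to_csv(path, index=False)


def read_drug_params_csv(path) -> dict[str, tuple[object, float]]:
    """Read the parameter CSV dialect back to {drug: (params, interval_h)}."""
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, tuple[object, float]] = {}
    for row in df.itertuples():
        if row.model == "linear":
            params = pk.LinearPKParams(
                volume=float(row.volume_l),
                absorption_rate=float(row.ka_per_h),
                elimination_rate=float(row.ke_per_h),
            )
        elif row.model == "mm":
            params = pk.MMPKParams(
                volume=float(row.volume_l),
                absorption_rate=float(row.ka_per_h),
                vmax=float(row.vm_ng_ml_h),
                km=float(row.km_ng_ml),
            )
        else:
            raise ValidationError(
                f"line {row.Index + 2}: unknown model {row.model!r}"
            )
        out[row.drug] = (params, float(row.interval_h))
    return out


def write_schedule_csv(path, doses_by_drug: Mapping[str, Iterable[float]]) -> None:
    rows = [
        {"drug": drug, "day": day, "dose_mg": float(dose)}
        for drug, doses in doses_by_drug.items()
        for day, dose in enumerate(doses, 1)
    ]
    pd.DataFrame(rows, columns=["drug", "day", "dose_mg"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_schedule_csv(path) -> dict[str, np.ndarray]:
    """{drug: per-day dose array} from a schedule CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"drug", "day", "dose_mg"} - set(df.columns)
    if missing:
        raise ValidationError(f"schedule CSV missing columns: {sorted(missing)}")
    out = {}
    for drug, sub in df.groupby("drug"):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy()
        if not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise ValidationError(f"schedule for {drug!r} has gaps in days")
        out[drug] = sub["dose_mg"].to_numpy(dtype=float)
    return out


def write_profile_csv(path, profile: pk.ConcentrationProfile) -> None:
    pd.DataFrame(
        {"time_h": profile.times, "conc_ng_ml": profile.concentrations}
    ).to_csv(path, index=False, float_format="%.17g")


def read_profile_csv(path) -> pk.ConcentrationProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    return pk.ConcentrationProfile(
        times=df["time_h"].to_numpy(dtype=float),
        concentrations=df["conc_ng_ml"].to_numpy(dtype=float),
    )


def write_sre_csv(path, records: Iterable[DrugSRERecord]) -> None:
    pd.DataFrame(
        [
            {
                "drug": r.drug,
                "population": r.population,
                "t_half_h": r.t_half,
                "rr_sre": r.rr_sre,
                "citation": r.citation,
            }
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_sre_csv(path) -> list[DrugSRERecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"drug", "population", "t_half_h", "rr_sre"} - set(df.columns)
    if missing:
        raise ValidationError(f"SRE CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples():
        try:
            records.append(
                DrugSRERecord(
                    drug=str(row.drug),
                    population=str(row.population),
                    t_half=float(row.t_half_h),
                    rr_sre=float(row.rr_sre),
                    citation=str(getattr(row, "citation", "")),
                )
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(
                f"SRE CSV line {row.Index + 2}: {exc}"
            ) from exc
    return records


def load_config(path) -> dict:
    """Load a YAML run configuration (see data/default_config.yaml)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg
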