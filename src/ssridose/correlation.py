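"""Half-life versus suicide-related-event (SRE) correlation analysis.

The loading rate of a once-daily drug is governed by its half-life:
accumulation to 90% of steady state takes t1/2 * ln(10)/ln(2) ~ 3.32
half-lives.  These analyses relate ln(t1/2) (or the inverse of that
90%-accumulation time) of SSRIs to the relative risk of suicide-related
events reported in placebo-controlled trials, using Pearson correlation
with a two-sided p-value from the exact t distribution with n-2 degrees
of freedom.

The drug-level (t1/2, RR) records are literature-sourced and ship as an
editable fixture; the statistics here make no claim about their
provenance beyond what the fixture's citation column records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "DrugSRERecord",
    "CorrelationReport",
    "correlate_ln_halflife",
    "correlate_inverse_t90",
    "time_to_90pct",
    "percent_change",
]

#: accumulation time to 90% of steady state, in half-lives: log2(10)
T90_HALF_LIVES = math.log(10.0) / math.log(2.0)


@dataclass(frozen=True)
class DrugSRERecord:
    """One (drug, population) row: terminal half-life in hours and the
    relative risk of suicide-related events."""

    drug: str
    population: str  # "adult" | "pediatric"
    t_half: float
    rr_sre: float
    citation: str = ""

    def __post_init__(self):
        if not self.t_half > 0:
            raise ValidationError("t_half must be strictly positive")
        if not self.rr_sre > 0:
            raise ValidationError("rr_sre must be strictly positive")


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation with the least-squares line for plotting."""

    n: int
    r: float
    p_value: float
    slope: float
    intercept: float


def _select(
    records: Iterable[DrugSRERecord], population: str | None
) -> list[DrugSRERecord]:
    if population is None:
        return list(records)
    return [r for r in records if r.population == population]


def _pearson_report(x: np.ndarray, y: np.ndarray) -> CorrelationReport:
    n = len(x)
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 records for a correlation, got {n}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationReport(
        n=n, r=float(r), p_value=float(p),
        slope=float(fit.slope), intercept=float(fit.intercept),
    )


def correlate_ln_halflife(
    records: Sequence[DrugSRERecord], population: str | None = None
) -> CorrelationReport:
    """Pearson correlation of ln(t1/2) against the relative risk of SREs,
    optionally restricted to one population.  The sign of r follows the
    natural axis orientation (x = ln t1/2, y = RR); with longer-lived
    drugs carrying lower risk it comes out negative."""
    rec = _select(records, population)
    x = np.array([math.log(r.t_half) for r in rec])
    y = np.array([r.rr_sre for r in rec])
    return _pearson_report(x, y)


def time_to_90pct(t_half: float) -> float:
    """Time to reach 90% of steady-state accumulation under first-order
    kinetics: t1/2 * ln(10)/ln(2)."""
    if not t_half > 0:
        raise ValidationError("t_half must be strictly positive")
    return t_half * T90_HALF_LIVES


def correlate_inverse_t90(
    records: Sequence[DrugSRERecord], population: str | None = None
) -> CorrelationReport:
    """Pearson correlation of 1/T90 (the reciprocal 90%-accumulation
    time, a direct loading-rate measure) against the relative risk."""
    rec = _select(records, population)
    x = np.array([1.0 / time_to_90pct(r.t_half) for r in rec])
    y = np.array([r.rr_sre for r in rec])
    return _pearson_report(x, y)


def percent_change(mean_a: float, mean_b: float) -> float:
    """100 * (mean_b - mean_a) / mean_b: with mean_a the treated group and
    mean_b the control, the 'percent less than control' when a < b."""
    if mean_b == 0:
        raise ValidationError("reference mean must be non-zero")
    return 100.0 * (mean_b - mean_a) / mean_b
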