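"""Publication-shaped figures: concentration time courses and
half-life/SRE correlation panels."""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from . import pk
from .correlation import (
    CorrelationReport,
    DrugSRERecord,
    correlate_inverse_t90,
    correlate_ln_halflife,
    time_to_90pct,
)

__all__ = ["plot_profiles", "plot_correlation_panels"]


def plot_profiles(
    profiles: Mapping[str, pk.ConcentrationProfile],
    path,
    title: str = "",
    hline: float | None = None,
) -> None:
    """Overlay concentration time courses (days on the x axis)."""
    fig, ax = plt.subplots(figsize=(7, 4.2))
    for label, profile in profiles.items():
        ax.plot(profile.times / 24.0, profile.concentrations, label=label, lw=1.2)
    if hline is not None:
        ax.axhline(hline, color="grey", ls="--", lw=0.8, label="steady-state mean")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("plasma concentration (ng/ml)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _panel(ax, x, y, labels, report: CorrelationReport, xlabel: str, title: str):
    ax.scatter(x, y, s=25, color="tab:blue", zorder=3)
    xs = np.linspace(min(x), max(x), 50)
    ax.plot(xs, report.intercept + report.slope * xs, color="tab:red", lw=1)
    for xi, yi, lab in zip(x, y, labels):
        ax.annotate(lab, (xi, yi), fontsize=6, textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel(xlabel)
    ax.set_ylabel("relative risk of SREs")
    ax.set_title(f"{title}\nr = {report.r:.2f}, p = {report.p_value:.3f}", fontsize=9)


def plot_correlation_panels(records: Sequence[DrugSRERecord], path) -> None:
    """Three panels: ln(t1/2) vs RR for adults and for children and
    adolescents, and the loading-rate measure 1/T90 vs RR (adults)."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.8))
    for ax, pop, label in zip(
        axes[:2], ("adult", "pediatric"), ("adults", "children & adolescents")
    ):
        rec = [r for r in records if r.population == pop]
        rep = correlate_ln_halflife(rec)
        x = [math.log(r.t_half) for r in rec]
        y = [r.rr_sre for r in rec]
        _panel(ax, x, y, [r.drug for r in rec], rep, "ln t1/2 (h)",
               f"half-life vs SRE risk, {label}")
    rec = [r for r in records if r.population == "adult"]
    rep = correlate_inverse_t90(rec)
    x = [1.0 / time_to_90pct(r.t_half) for r in rec]
    y = [r.rr_sre for r in rec]
    _panel(axes[2], x, y, [r.drug for r in rec], rep, "1 / T90 (1/h)",
           "loading rate vs SRE risk, adults")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
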