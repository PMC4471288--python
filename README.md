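# ssridose

Pharmacokinetic simulation and dose-titration tooling for selective
serotonin reuptake inhibitors (SSRIs), built around a safety question in
pediatric depression: acute SSRI exposure transiently *suppresses*
serotonergic output (via 5-HT1A autoreceptor activation) and is
associated with suicide-related events (SREs) early in treatment, and
the faster a drug loads into plasma, the stronger that early hit.
Fluoxetine — the slowest-loading SSRI — carries the lowest SRE risk, so
this package (a) quantifies the half-life/risk relationship and
(b) computes escalating 30-day dose schedules that make five
faster-clearing SSRIs accumulate exactly as slowly as fluoxetine does.

It is intended for pharmacometric and computational-psychiatry work.
It is **not** clinical dosing advice.

## Model

Plasma concentration follows a one-compartment model with first-order
absorption and either first-order or saturable elimination. For a dose
*D* (mg) into apparent volume *V* (l), with absorption constant
K<sub>01</sub> (1/h):

    dC/dt = K01 · (D·10³/V) · exp(−K01·t) − Vm · C / (Km + C)

summed over all past doses (concentrations in ng/ml; the saturable term
reduces to first-order elimination ke·C when C ≪ Km, with
ke = Vm/Km). Fluoxetine, paroxetine and fluvoxamine use the
Michaelis–Menten form; sertraline, citalopram and venlafaxine (+ its
active metabolite, treated as one moiety) are linear, solved by analytic
superposition of bi-exponential single-dose terms.

The pipeline has four stages:

1. **Calibration** — linear drugs from published (V, t½, T<sub>max</sub>)
   via ke = ln2/t½ and the peak-time identity
   T<sub>max</sub> = ln(k<sub>a</sub>/k<sub>e</sub>)/(k<sub>a</sub>−k<sub>e</sub>);
   saturable drugs by bounded least squares against their single-dose
   (C<sub>max</sub>, T<sub>max</sub>, t½) triple.
2. **Reference curve** — fluoxetine 40 mg once daily; each day's mean
   concentration as a fraction of the steady-state mean (~0.21 on day 1,
   ~1.0 by day 30).
3. **Titration** — for each drug, day *i*'s dose is root-found so the
   simulated day-*i* mean equals fraction<sub>i</sub> × the drug's own
   steady-state mean, conditioning on all previous doses.
4. **Risk correlation** — Pearson correlation (exact t-based two-sided
   p) of ln t½, and of the loading-rate measure
   1/T90 = ln2/(ln10 · t½), against the relative risk of SREs.

## Worked example

```python
import ssridose as sd
from ssridose import datasets

flx = datasets.fluoxetine_params()          # V=1033 l, K01=0.53/h, Vm=6.5, Km=448
cmax, tmax, t_half = sd.single_dose_metrics(sd.single_dose_profile(flx, 40.0))
means = sd.regimen_daily_means(flx, 40.0, interval=24, days=30)
print(round(cmax, 1), round(t_half, 1))     # 35.2 47.8
print(round(means[0], 1), round(means[29], 1))  # 30.8 147.7

ser = datasets.build_drug_registry()["sertraline"]
ref = sd.build_reference(flx, dose=40.0, days=30)
result = sd.generate_titration(ser.params, ser.standard_dose, ser.interval, ref)
print(round(result.doses[0], 1), round(result.doses[29], 1))  # 24.1 50.9
print(round(result.achieved_daily_means[29], 1))              # 56.8
```

A single 40 mg fluoxetine dose peaks at ~35 ng/ml and decays with a
~48 h terminal half-life; daily dosing climbs from a 30.8 ng/ml day-1
mean to ~148 ng/ml by day 30. The solved sertraline schedule starts
near half the maintenance dose (24 mg) and escalates to ~51 mg, pinning
sertraline's month-long accumulation onto fluoxetine's curve (its day-30
mean, 56.8 ng/ml, is its own steady state).

The `examples/` scripts walk each capability end to end, and a thin CLI
wraps the same functions:

```bash
ssridose --out out make-table          # 30-day dose table for all five drugs
ssridose --out out simulate sertraline # constant vs titrated overlay plot
ssridose --out out correlate           # half-life vs SRE-risk panels
```

## Layout

- `src/ssridose/pk.py` — simulators, daily means, single-dose metrics,
  steady state
- `src/ssridose/calibration.py` — parameter derivation and forward checks
- `src/ssridose/titration.py` — reference fractions and dose solving
- `src/ssridose/correlation.py` — half-life vs SRE-risk statistics
- `src/ssridose/synthetic.py` — seeded generators for drugs and risk records
- `src/ssridose/datasets.py`, `src/ssridose/data/` — bundled published
  assumptions, published schedules, illustrative SRE fixture
- `docs/methods.md` — model, numerical choices and limitations
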