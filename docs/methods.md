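# Methods

## Model and assumptions

All drugs are described by a single well-stirred plasma compartment with
first-order absorption from a depot. Elimination is either first-order
(rate constant ke, 1/h) or Michaelis–Menten (maximum rate Vm in
ng·ml⁻¹·h⁻¹ and Michaelis constant Km in ng/ml, so the instantaneous
clearance constant is Vm/(Km+C) and tends to ke ≡ Vm/Km as C → 0).
Doses are absolute milligrams for a 70 kg adult; a dose D contributes
D·10³/V ng/ml to the depot (mg/l → ng/ml is a factor of 1000). Dose 1
is given at t = 0 and "day i" is the window [24(i−1), 24i] hours.
Multi-dose schedules superpose in the absorption depot; the saturable
elimination acts on the total concentration. No protein binding,
peripheral compartments, metabolite kinetics (venlafaxine and
O-desmethylvenlafaxine are folded into one combined moiety with a single
published V, t½ and T<sub>max</sub>) or between-subject variability.

## Numerics

- **Linear model**: evaluated analytically as a superposition of
  (D/V)·k<sub>a</sub>/(k<sub>a</sub>−k<sub>e</sub>)·(e^(−k<sub>e</sub>τ) −
  e^(−k<sub>a</sub>τ)) terms; no integration error. The degenerate case
  k<sub>a</sub> = k<sub>e</sub> is rejected at construction (no SSRI sits
  near it, and the synthetic generator stays away from it by design).
- **Michaelis–Menten model**: stiff-capable adaptive integration (LSODA,
  rtol 1e-9, atol 1e-12) with the depot carried as an explicit state, so
  each dose is an impulse on the depot between smooth segments and the
  integrator state at a day boundary can be cached and reused by the
  titration solver.
- **Output grid**: 0.1 h by default. Daily means are trapezoidal over
  the 24 h window (endpoints interpolated); at 0.1 h the quadrature
  error is far below the 3-significant-figure resolution of the
  quantities reported.
- **Steady state**: `steady_state_cave` reports the daily mean on the
  first day whose relative change from the previous day is < 1e-3, with
  a 60-day cap. The titration stage instead anchors on the *day-60*
  daily mean (`plateau_daily_mean`): the first-converged-day value sits
  a few tenths of a percent below the plateau, which would push the
  day-30 loading fraction marginally above 1; the plateau convention
  keeps fractions in (0, 1].

## Single-dose metrics

C<sub>max</sub> and T<sub>max</sub> are the grid maximum refined by a
local cubic-spline fit. The half-life is the **terminal (λ<sub>z</sub>)
half-life**: ln 2 divided by the slope of a log-linear regression over
the deepest available decade of the post-peak tail, capped above at
C<sub>max</sub>/8. Two alternatives were considered and rejected:

- *Peak-to-half-peak time.* For fluoxetine's published constants this
  measures 52.4 h, not the published 48 h: at C<sub>max</sub> ≈ 35 ng/ml
  the concentration is not negligible against Km = 448 (the apparent
  clearance constant is ~7% below its terminal value) and residual
  absorption flattens the early decline further. It also biases linear
  calibration round-trips, because ln2/ke only equals the measured
  half-life asymptotically.
- *ln2·Km/Vm analytically.* Exact for the saturable model at C → 0 but
  unavailable for measured profiles and synthetic observables, which
  must go through the same estimator the calibration consumes.

The terminal regression yields ln2/ke exactly for linear drugs and
47.8 h for fluoxetine (published: 48 h). A profile whose tail never
reaches C<sub>max</sub>/8 raises a horizon error rather than returning a
biased estimate.

## Calibration

Linear drugs: ke = ln2/t½ and k<sub>a</sub> from bracketed root-finding
on the peak-time identity; no solution exists once
T<sub>max</sub> ≥ 1/k<sub>e</sub>, which is reported as a calibration
error. Saturable drugs: bounded least squares in log-parameter space on
the relative residuals of (C<sub>max</sub>, T<sub>max</sub>, t½) from a
forward single-dose simulation; the fit must close to within 1%. Three
observables cannot pin four parameters: with a Km prior the remaining
three are well determined (synthetic round-trips recover them to ~1e-6);
without one the solver returns a deterministic minimum-residual point on
the degenerate family and warns. Fluoxetine's published constants are
used verbatim rather than refitted; paroxetine and fluvoxamine, whose
constants were never published, are calibrated with Km free, so their
absolute concentration scales (e.g. the fluvoxamine steady-state mean)
are one admissible choice among many — every *relative* (fraction-
matching) property is insensitive to that choice.

## Titration

The reference curve is fluoxetine 40 mg once daily: daily means divided
by the day-60 plateau give 30 loading fractions (0.208 on day 1,
0.998 on day 30). Each titrated drug's targets are these fractions
times the drug's own plateau under its standard maintenance regimen
(paroxetine 41.4, citalopram 20.7, sertraline 51.0, venlafaxine 228.6 mg
once daily; fluvoxamine 41.0 mg twice daily — the published day-30
doses, overridable in the config). Daily doses are solved sequentially
by Brent root-finding on the simulated day mean, which is strictly
increasing in the dose, over [0, 10× the standard dose]; the achieved
mean must sit within 0.1% of the target. Twice-daily drugs take two
equal doses per day. Optional rounding (round-half-up to a per-drug
increment) is applied *before* a dose is fixed into the history, so
later days compensate for rounding drift. Reported achieved means come
from one final re-simulation of the complete solved schedule.

Solved doses are non-decreasing across days for every once-daily drug.
The twice-daily drug front-loads day 1 (its second dose contributes only
half a day to the day-1 mean), so the exact solution can shed a little
dose on day 2 and is monotone from there — the published fluvoxamine
column shows the same near-flat day-1→2 step.

## Risk correlation

Pearson r between ln t½ (or 1/T90, with T90 = t½·ln10/ln2 ≈ 3.32
half-lives, the time to 90% of steady-state accumulation) and the
relative risk of suicide-related events; two-sided p from the exact t
distribution with n−2 degrees of freedom (scipy), cross-checked in the
tests against a label-permutation oracle. Significance threshold 0.05.
Axis orientation is the natural one (x = half-life measure, y = risk),
so longer-lived drugs correlate *negatively* with risk on the ln t½
axis and positively on the 1/T90 axis; the sign is reported, not
folded away. The bundled `sre_records_synthetic.csv` is an illustrative
stand-in assembled from public PK half-lives and the 2004 FDA pediatric
meta-analysis risk ratios — the drug-level pairs behind the original
figure were never printed — so automated checks treat it as smoke-level
data; all hard statistical tests run on seeded synthetic records.

## Synthetic data

`gen_pk_drug` draws V ∈ [100, 2000] l, t½ ∈ [5, 60] h,
T<sub>max</sub> ∈ [2, 10] h, Km ∈ [50, 1000] ng/ml and a reference dose
∈ [20, 80] mg — ranges bracketing all six bundled drugs — and caps
T<sub>max</sub> at 0.5/k<sub>e</sub> (beyond ~1/k<sub>e</sub> no
absorption rate can produce the peak; near it, absorption and
elimination become practically indistinguishable, which no published
SSRI exhibits). Observables are *measured* from a forward simulation
through `single_dose_metrics`, never computed from the parameters, so
calibration round-trips exercise the full pipeline. `gen_sre_records`
draws (ln t½, RR) from a bivariate normal with a controlled correlation
(RR floored at 0.05 for positivity; with the default location/scale the
floor essentially never binds). Both generators are pure functions of
their seed. What the generators do **not** emulate: assay noise,
sampling-time sparsity, between-subject variability, and model
misspecification — passing round-trips show the estimators are
consistent with the model, not that the model fits any particular
patient.

## Known limitations and discrepancies

- Simulating the published citalopram dose column under the stated
  parameters gives a day-30 mean of 51.8 ng/ml against a published
  50.1 (+3.3%); the published value coincides with the steady-state
  mean of a 20.0 mg/day regimen rather than of the printed 20.7 mg
  column, so the published dose and concentration columns appear
  mutually inconsistent under the stated model. Sertraline shows the
  same effect at +2.1%, inside tolerance. The package reproduces the
  model, not the inconsistency.
- The published venlafaxine column sits ~9% below the stated
  combined-moiety model; the parameters are used verbatim and the gap is
  left visible.
- Problem sizes: 30–60 simulated days on a 0.1 h grid, single-dose
  horizons of 10–25 half-lives for metric extraction; all stages run in
  seconds on one CPU, and the full test suite in well under a minute.
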