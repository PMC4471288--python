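"""Calibration round-trip on a synthetic drug.

Draws a random saturable drug, measures its single-dose observables by
forward simulation (exactly what a PK paper would print), re-calibrates
with the true Km supplied, and compares recovered to generating
parameters.
"""

import ssridose as sd

spec = sd.SyntheticDrugSpec(seed=2024, model="mm")
params, obs = sd.gen_pk_drug(spec)

print(f"generated drug:  V={params.volume:.0f} l  K01={params.absorption_rate:.3f} /h"
      f"  Vm={params.vmax:.2f}  Km={params.km:.0f}")
print(f"observables:     Cmax={obs.cmax:.1f} ng/ml  Tmax={obs.tmax:.1f} h"
      f"  t1/2={obs.t_half:.1f} h  (after {obs.ref_dose:.0f} mg)")

recovered = sd.calibrate_mm(obs, km_prior=params.km)
print("recovered:      ", end="")
for field in ("volume", "absorption_rate", "vmax"):
    true, est = getattr(params, field), getattr(recovered, field)
    print(f"{field} {est:.4g} ({(est - true) / true:+.2%})", end="  ")
print()
print()
print("With Km pinned the three remaining constants come back to a small")
print("fraction of a percent - the observables carry exactly the")
print("information the calibration consumes, because they were produced")
print("by the same forward model.")
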