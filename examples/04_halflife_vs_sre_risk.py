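"""Half-life versus suicide-related-event (SRE) risk.

Runs the three correlation panels on the bundled illustrative records
(ln t1/2 vs relative risk for adults and for children/adolescents, and
the loading-rate measure 1/T90 vs relative risk), and the worked
percent-change computation from the behavioural experiment summary.
"""

import ssridose as sd
from ssridose import datasets

records = datasets.load_sre_fixture()

for label, fn, pop in (
    ("ln t1/2 vs RR, adults      ", sd.correlate_ln_halflife, "adult"),
    ("ln t1/2 vs RR, pediatric   ", sd.correlate_ln_halflife, "pediatric"),
    ("1/T90  vs RR, adults       ", sd.correlate_inverse_t90, "adult"),
):
    rep = fn(records, population=pop)
    print(f"{label} n={rep.n}  r={rep.r:+.3f}  p={rep.p_value:.4f}")

print()
print(f"T90 (time to 90% of steady state) for t1/2 = 48 h: "
      f"{sd.time_to_90pct(48.0):.0f} h (~{sd.time_to_90pct(48.0)/24:.1f} days)")
print()
print("Negative r on ln t1/2 and positive r on 1/T90 say the same thing:")
print("drugs that load faster (shorter half-life) carry higher SRE risk.")
print("These records are an illustrative stand-in for the literature")
print("values, so treat the p-values as demonstrations, not findings.")
print()
change = sd.percent_change(5.67, 20.03)
print(f"worked example: open-arm time 5.67 s (treated) vs 20.03 s (control)"
      f" -> {change:.1f}% less, i.e. ~{round(change)}% reduction")
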