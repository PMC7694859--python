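"""Classify breeds as deviant against the population intervals.

Fits the population model on the nonsighthound group, then counts per
breed how many measurements fall above/below the 95% PI at each dog's own
body weight.  A breed with more than 10% on either side needs
breed-specific reference values.
"""

import echoref as er

cohort = er.generate_cohort(er.SimConfig(seed=0, truth=er.default_truth()))
screened, _ = er.screen_cohort(cohort)
group = screened.nonsighthound()

fits = {v: er.fit_allometric(group, v) for v in ("LVDd", "LVDs", "LVWd")}
rows = er.breed_deviance(screened.healthy(), fits, cutoff_pct=10.0)

print(er.deviance_table(rows).to_string(index=False))
print()
for r in rows:
    if r.deviant_any():
        flagged = [
            f"{v}{'↑' if s['above_deviant'] else '↓'}"
            for v, s in r.per_variable.items()
            if s["above_deviant"] or s["below_deviant"]
        ]
        print(f"deviant: {r.breed:20s} {' '.join(flagged)}")
print("\n↑ = >10% of measurements above the PI (enlarged relative to BW),")
print("↓ = >10% below.  Sighthound chambers flag high, Newfoundland low.")
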