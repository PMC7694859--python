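"""Fit the allometric model and build 95% prediction intervals.

Fits log(LVDd) on log(BW) by OLS, giving the scaling law LVDd = a * BW**b,
then evaluates the exact prediction interval (with leverage term) and the
approximate on-the-spot interval (constants times BW**b) at 25 kg.
"""

import echoref as er

cohort = er.generate_cohort(er.SimConfig(seed=0, truth=er.default_truth()))
screened, report = er.screen_cohort(cohort)
group = screened.nonsighthound()

fit = er.fit_allometric(group, "LVDd")
print(f"LVDd = {fit.a:.2f} * BW^{fit.b:.3f}   "
      f"(n={fit.n}, R^2={fit.r2:.3f}, sigma={fit.sigma:.4f} on log scale)")

for method in ("exact", "approx"):
    pi = er.prediction_interval(fit, 25.0, method=method)
    print(f"25 kg, {method:6s}: mean {pi.mean:.2f} cm, "
          f"95% PI ({pi.lower:.2f}, {pi.upper:.2f}) cm")

consts = er.index_constants(fit, group)
pcts = sorted(consts.constants)
print("\nindexing constants (value of LVDd / BW^b at each percentile):")
print("  " + "  ".join(f"p{p:g}={consts.constants[p]:.2f}" for p in pcts))
print("\nMultiply a constant by BW^b to reconstruct that percentile curve;")
print("the 2.5/97.5 pair gives the approximate 95% reference band.")
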