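"""Validate the allometric model with a penalized-spline smooth, and
compare the all vs immaculate screening groups.

A P-spline GAM of the measurement against BW**b should be a straight line
if the power law is adequate; the maximum relative deviation between
smooth and line operationalizes the visual check.  The two health-status
groups are compared by the mean difference between their upper PI limits.
"""

import numpy as np

import echoref as er

cohort = er.generate_cohort(er.SimConfig(seed=0, truth=er.default_truth()))
screened, _ = er.screen_cohort(cohort)
group_all = screened.nonsighthound()
group_imm = screened.immaculate()

fit = er.fit_allometric(group_all, "LVDd")
report = er.linearity_check(fit, group_all)
print(f"LVDd linearity: max |smooth - line| / range = "
      f"{report.max_rel_dev:.4f} (edf {report.edf:.1f}) -> "
      f"{'adequate' if report.adequate else 'NOT adequate'}")

grid = [10, 15, 20, 25, 30, 40, 50, 60]
comp = er.group_upper_limit_difference(group_all, group_imm, "LVDd", grid)
print(f"mean upper-limit difference (all - immaculate): "
      f"{comp.mean_upper_diff:+.4f} cm "
      f"({100 * comp.mean_upper_diff / np.mean(comp.upper_a):+.2f}% of the limit)")
print(f"additive-model group effect: {comp.group_effect:+.4f} cm")
print("\nBoth groups are drawn from one truth here, so the difference is")
print("negligible — the justification for pooling them in the analysis.")
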