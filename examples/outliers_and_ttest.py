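"""Per-group outlier rejection and a two-sample comparison.

Applies the modified Thompson tau rule to a small sample containing a
gross outlier, then compares two groups with a pooled-variance t-test,
one- and two-tailed.
"""

import zfquant as zq

sample = [0.42, 0.45, 0.44, 0.47, 0.43, 0.91]
report = zq.thompson_tau_outliers(sample, alpha=0.05)
print(f"input values : {sample}")
print(f"removed      : {report.removed}")
print(f"kept         : {report.kept}")
print()

control = [0.52, 0.55, 0.49, 0.58, 0.53, 0.51, 0.56, 0.54]
treated = [0.46, 0.49, 0.44, 0.50, 0.47, 0.43, 0.48, 0.45]
two = zq.t_test(control, treated, tail="two")
one = zq.t_test(control, treated, tail="greater")
print(f"two-tailed : t={two.statistic:.3f}, df={two.degrees_of_freedom:.0f}, "
      f"p={two.p_value:.4f}")
print(f"one-tailed : t={one.statistic:.3f}, df={one.degrees_of_freedom:.0f}, "
      f"p={one.p_value:.4f}")
print()
print("The one-tailed p is half the two-tailed p when the observed")
print("difference lies in the hypothesised direction.")
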