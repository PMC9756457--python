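"""Estimate individual-level prevalence from pooled assays.

Pools of k specimens are assayed together; a pool is positive when any
member is positive.  From the count of positive pools the Burrows estimator
recovers the individual-level prevalence with most of the pooling bias of
the naive MLE removed, together with a variance for downstream testing.
"""

from poolscreen import burrows_estimate, z_statistic

# 100 pools of 5 cases, 40 tested positive; same layout for controls with 25
case = burrows_estimate(x=40, n=100, k=5)
control = burrows_estimate(x=25, n=100, k=5)

print(f"case prevalence:    {case.p_hat:.4f}  (variance {case.variance:.3e})")
print(f"control prevalence: {control.p_hat:.4f}  (variance {control.variance:.3e})")

z, p = z_statistic(case, control)
print(f"z = {z:.3f}, two-sided p = {p:.4f}")
print()
print("The prevalences are per-individual despite only 200 assays being used")
print("for 1,000 people; the z-test screens antibodies for case-control")
print("differences using pooled data only.")
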