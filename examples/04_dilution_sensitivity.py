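"""Effect of pooled-test dilution error on the two-phase design.

Pooling specimens can dilute a single positive sample below an assay's
detection limit.  The model: a truly positive pool tests positive with
probability `sensitivity` (specificity stays perfect).  This script
evaluates the two-phase design at sensitivities 1.0, 0.98 and 0.95 on
shared simulated cohorts.
"""

from poolscreen import (
    SimulationConfig,
    build_calibration_table,
    summaries_frame,
    sweep_sensitivity,
)

cfg = SimulationConfig(n_antibodies=800, n_signal=200)
calib = build_calibration_table(0.3, 0.05, (500, 500, 5), reps=2000, seed=42)

summaries = sweep_sensitivity(
    [1.0, 0.98, 0.95], cfg, k=5, c1=0.3, calibration=calib, reps=60, seed=9
)

df = summaries_frame(summaries)
print(df[["sensitivity", "power", "type1", "expected_tests"]].to_string(index=False))
print()
print("Moderate dilution error barely moves power or type-I error: a missed")
print("pool mainly removes a few individuals from the reconstructed table,")
print("and slightly lowers the assay count (missed pools are never retested).")
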