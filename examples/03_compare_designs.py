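"""Compare the three screening designs on one simulated cohort.

Simulates a case-control serologic screen (reduced to 1,500 antibodies for
speed), runs individual case-control testing, standard group testing, and
the two-phase group-testing design, and prints each design's significant
antibody count and total assay consumption.
"""

from poolscreen import (
    SimulationConfig,
    build_calibration_table,
    count_tests,
    run_case_control,
    run_standard_gt,
    run_two_phase,
    simulate_cohort,
)

cfg = SimulationConfig(n_antibodies=1500, n_signal=200, seed=7)
matrix = simulate_cohort(cfg)
print(f"cohort: {cfg.n_cases} cases + {cfg.n_controls} controls, "
      f"{cfg.n_antibodies} antibodies ({cfg.n_signal} with a true effect)\n")

calib = build_calibration_table(0.3, 0.05, (500, 500, 5), reps=2000, seed=42)

results = [
    run_case_control(matrix, alpha=0.05),
    run_standard_gt(matrix, k=5, alpha=0.05, seed=1),
    run_two_phase(matrix, k=5, c1=0.3, calibration=calib, seed=1),
]

print(f"{'design':<14}{'significant':>12}{'true pos':>10}{'total assays':>14}")
for res in results:
    sig = res.significant
    total, _, _ = count_tests(res)
    print(f"{res.design_name:<14}{int(sig.sum()):>12}{int(sig[:200].sum()):>10}"
          f"{total:>14,}")

print()
print("Standard group testing reproduces the case-control calls exactly at")
print("perfect sensitivity while skipping assays on negative pools; the")
print("two-phase design reduces assays further by retesting only antibodies")
print("that pass the pooled z-screen, at nearly identical power.")
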