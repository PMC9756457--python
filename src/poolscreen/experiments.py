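"""Monte-Carlo evaluation of screening designs: power, type-I error, cost.

The harness simulates replicated cohorts under the probit random-effect
model and runs one or more designs on each, reporting

* **power** — rejection rate over the signal antibodies (those with a true
  case effect),
* **type-I error** — rejection rate over the null antibodies, and
* **expected tests** — the mean total assay count,

each with a Monte-Carlo standard error.  A seed ladder (master seed ->
per-replicate cohort seed -> per-design stream) guarantees that designs
compared on the same master seed see identical cohorts, giving paired
comparisons with reduced between-design variance.

Because the designs apply no multiplicity adjustment, each antibody's
operating characteristics do not depend on how many other antibodies are in
the cohort; power and type-I error can therefore be estimated on cohorts
with fewer null antibodies than a real screen, while expected test counts
scale with the antibody count and must be measured at the intended scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationTable, build_calibration_table, read_calibration_csv, write_calibration_csv
from .designs import DesignResult, run_case_control, run_standard_gt, run_two_phase
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "EvaluationSummary",
    "evaluate_design",
    "sweep_c1",
    "sweep_sensitivity",
    "get_or_build_calibration",
    "summaries_frame",
]


@dataclass(frozen=True)
class EvaluationSummary:
    """Operating characteristics of one design configuration.

    ``power``/``type1`` are rejection rates over signal/null antibodies
    pooled across replicates; ``*_se`` are Monte-Carlo standard errors of
    the replicate means (sd across replicates / sqrt(reps)).  ``power`` is
    NaN when the simulation contains no signal antibodies.
    """

    design_name: str
    k: int | None
    c1: float | None
    sensitivity: float
    alpha: float
    reps: int
    n_signal: int
    n_null: int
    power: float
    type1: float
    expected_tests: float
    power_se: float
    type1_se: float
    tests_se: float


def _cohort_seed(seed: int, rep: int) -> list[int]:
    return [seed, rep]


def _design_seed(seed: int, rep: int) -> int:
    # independent 31-bit stream per (master seed, replicate)
    ss = np.random.SeedSequence([seed, rep, 7])
    return int(ss.generate_state(1)[0] >> 1)


def _run(design: str, matrix, *, k, c1, alpha, calibration, sensitivity, seed) -> DesignResult:
    if design == "case_control":
        return run_case_control(matrix, alpha=alpha)
    if design == "standard_gt":
        return run_standard_gt(matrix, k=k, alpha=alpha, sensitivity=sensitivity, seed=seed)
    if design == "two_phase":
        if calibration is None:
            raise ValueError("two_phase evaluation requires a calibration table")
        return run_two_phase(matrix, k=k, c1=c1, calibration=calibration,
                             sensitivity=sensitivity, seed=seed)
    raise ValueError(f"unknown design {design!r}")


def evaluate_design(
    design: str,
    sim_config: SimulationConfig,
    reps: int,
    seed: int,
    *,
    k: int | None = None,
    c1: float | None = None,
    alpha: float = 0.05,
    calibration: CalibrationTable | None = None,
    sensitivity: float = 1.0,
) -> EvaluationSummary:
    """Estimate power, type-I error and expected tests over fresh cohorts.

    Parameters
    ----------
    design : {"case_control", "standard_gt", "two_phase"}
    sim_config : SimulationConfig
        Generative model for each replicate's cohort (its ``seed`` field is
        ignored; cohort seeds come from the ladder).
    reps : int
        Number of replicated cohorts.
    seed : int
        Master seed of the ladder.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    n_signal = sim_config.n_signal
    n_null = sim_config.n_antibodies - n_signal
    sig_rates, null_rates, totals = [], [], []
    for rep in range(reps):
        cfg = dataclasses.replace(sim_config, seed=_cohort_seed(seed, rep))
        matrix = simulate_cohort(cfg)
        result = _run(design, matrix, k=k, c1=c1, alpha=alpha,
                      calibration=calibration, sensitivity=sensitivity,
                      seed=_design_seed(seed, rep))
        rejected = result.significant
        if n_signal:
            sig_rates.append(rejected[:n_signal].mean())
        if n_null:
            null_rates.append(rejected[n_signal:].mean())
        totals.append(result.total_tests)
    def mean_se(values):
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            return float("nan"), float("nan")
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
        return float(arr.mean()), se
    power, power_se = mean_se(sig_rates)
    type1, type1_se = mean_se(null_rates)
    expected, tests_se = mean_se(totals)
    return EvaluationSummary(
        design_name=design, k=k, c1=c1, sensitivity=sensitivity, alpha=alpha,
        reps=reps, n_signal=n_signal, n_null=n_null,
        power=power, type1=type1, expected_tests=expected,
        power_se=power_se, type1_se=type1_se, tests_se=tests_se,
    )


def sweep_c1(
    c1_values,
    sim_config: SimulationConfig,
    k: int,
    reps: int,
    seed: int,
    calibrations: dict,
    *,
    alpha: float = 0.05,
    sensitivity: float = 1.0,
) -> list[EvaluationSummary]:
    """Evaluate the two-phase design over a grid of phase-1 cutoffs.

    ``calibrations`` maps each ``c1`` to its own calibration table (the
    phase-2 cutoff depends on ``c1``).  All cutoffs share cohort seeds, so
    differences between rows are paired.
    """
    summaries = []
    for c1 in c1_values:
        if c1 not in calibrations:
            raise ValueError(f"no calibration table supplied for c1={c1}")
        summaries.append(evaluate_design(
            "two_phase", sim_config, reps, seed, k=k, c1=c1, alpha=alpha,
            calibration=calibrations[c1], sensitivity=sensitivity,
        ))
    return summaries


def sweep_sensitivity(
    sensitivity_values,
    sim_config: SimulationConfig,
    k: int,
    c1: float,
    calibration: CalibrationTable,
    reps: int,
    seed: int,
    *,
    alpha: float = 0.05,
) -> list[EvaluationSummary]:
    """Evaluate the two-phase design under varying pooled-test sensitivity.

    Models dilution error: a truly positive pool tests negative with
    probability ``1 - sensitivity``.  Cohort seeds are shared across
    sensitivity values.
    """
    return [
        evaluate_design(
            "two_phase", sim_config, reps, seed, k=k, c1=c1, alpha=alpha,
            calibration=calibration, sensitivity=s,
        )
        for s in sensitivity_values
    ]


def get_or_build_calibration(
    cache_path,
    c1: float,
    alpha: float,
    design_params: tuple[int, int, int],
    reps: int,
    seed: int,
    min_advanced: int = 100,
) -> CalibrationTable:
    """Load a cached calibration table or build and cache it.

    An existing file must match the requested design exactly, including the
    replicate count — the harness never silently recalibrates at a
    different Monte-Carlo effort.
    """
    import os

    n_cases, n_controls, k = design_params
    expect = {"alpha": alpha, "c1": c1, "n_cases": n_cases,
              "n_controls": n_controls, "k": k, "reps": reps}
    if cache_path is not None and os.path.exists(cache_path):
        return read_calibration_csv(cache_path, expect=expect)
    table = build_calibration_table(c1, alpha, design_params, reps, seed,
                                    min_advanced=min_advanced)
    if cache_path is not None:
        write_calibration_csv(table, cache_path)
    return table


def summaries_frame(summaries) -> pd.DataFrame:
    """Tabulate EvaluationSummary records, one row per configuration."""
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])
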