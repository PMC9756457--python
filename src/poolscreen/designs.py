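"""The three antibody-screening designs and their exact assay accounting.

* **Case-control**: every individual is assayed for every antibody and each
  antibody is judged by a Fisher exact test at level ``alpha``.  Cost:
  individuals x antibodies.
* **Standard group testing**: pools are assayed for every antibody; every
  observed-positive pool is fully retested to reconstruct individual data,
  then Fisher tests at ``alpha``.  Cost: pools x antibodies + retests.
* **Two-phase group testing**: pooled data feed a per-antibody z-test on
  Burrows prevalence estimates; only antibodies with phase-1 p-value below
  ``c1`` advance, and only their observed-positive pools are retested.  The
  reconstructed table is judged against the prevalence-calibrated cutoff
  ``c2``.  Cost: pools x antibodies + retests for advancing antibodies only.

All designs return a :class:`DesignResult` carrying per-antibody decisions
and a double-entry test count (phase-1 + phase-2 = total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .calibration import CalibrationTable, lookup_c2
from .estimators import _burrows_p, _burrows_var, _z_pvalue, fisher_pvalues
from .pooling import AntibodyMatrix, assign_pools, pool_outcomes, reconstruct_individuals

__all__ = [
    "DesignResult",
    "run_case_control",
    "run_standard_gt",
    "run_two_phase",
    "count_tests",
    "write_result",
    "read_result",
]


@dataclass
class DesignResult:
    """Per-antibody decisions and assay accounting for one design run.

    ``table`` has one row per antibody with columns ``antibody_id``,
    ``phase1_p``, ``advanced``, ``final_p``, ``significant`` (phase fields
    are NaN/NA for designs without a pooled screen).
    """

    design_name: str
    table: pd.DataFrame
    total_tests: int
    phase1_tests: int
    phase2_tests: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_tests != self.phase1_tests + self.phase2_tests:
            raise ValueError("test accounting must satisfy total = phase1 + phase2")

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant"].to_numpy(dtype=bool)


def _result_table(antibody_ids, phase1_p, advanced, final_p, significant) -> pd.DataFrame:
    return pd.DataFrame({
        "antibody_id": antibody_ids,
        "phase1_p": phase1_p,
        "advanced": advanced,
        "final_p": final_p,
        "significant": significant,
    })


def _case_control_counts(matrix: AntibodyMatrix) -> tuple[np.ndarray, np.ndarray, int, int]:
    cases, controls = matrix.case_rows, matrix.control_rows
    a = matrix.outcomes[cases].sum(axis=0)
    c = matrix.outcomes[controls].sum(axis=0)
    return a, c, cases.size, controls.size


def run_case_control(matrix: AntibodyMatrix, alpha: float = 0.05) -> DesignResult:
    """Individual-testing design: Fisher's exact test per antibody at ``alpha``."""
    a, c, n1, n2 = _case_control_counts(matrix)
    pvals = fisher_pvalues(a, c, n1, n2)
    total = matrix.n_individuals * matrix.n_antibodies
    table = _result_table(matrix.antibody_ids, np.nan, pd.NA, pvals, pvals < alpha)
    return DesignResult(
        design_name="case_control", table=table,
        total_tests=total, phase1_tests=total, phase2_tests=0,
        params={"alpha": alpha},
    )


def run_standard_gt(
    matrix: AntibodyMatrix,
    k: int,
    alpha: float = 0.05,
    sensitivity: float = 1.0,
    seed: int | None = None,
) -> DesignResult:
    """Group-testing design: pool everything, retest all positive pools.

    With perfect sensitivity the reconstruction is lossless, so the
    significance calls coincide exactly with the case-control design on the
    same matrix.
    """
    rng = np.random.SeedSequence(seed)
    s_assign, s_pool = (int(c.generate_state(1)[0] >> 1) for c in rng.spawn(2))
    scheme = assign_pools(matrix.labels, k, seed=s_assign)
    pooled = pool_outcomes(matrix, scheme, sensitivity=sensitivity, seed=s_pool)
    recon, retests = reconstruct_individuals(matrix, pooled, scheme)
    cases, controls = matrix.case_rows, matrix.control_rows
    a = recon[cases].sum(axis=0)
    c = recon[controls].sum(axis=0)
    pvals = fisher_pvalues(a, c, cases.size, controls.size)
    phase1 = scheme.n_groups * matrix.n_antibodies
    table = _result_table(matrix.antibody_ids, np.nan, pd.NA, pvals, pvals < alpha)
    return DesignResult(
        design_name="standard_gt", table=table,
        total_tests=phase1 + retests, phase1_tests=phase1, phase2_tests=retests,
        params={"alpha": alpha, "k": k, "sensitivity": sensitivity, "seed": seed},
    )


def run_two_phase(
    matrix: AntibodyMatrix,
    k: int,
    c1: float,
    calibration: CalibrationTable,
    sensitivity: float = 1.0,
    seed: int | None = None,
) -> DesignResult:
    """Two-phase design: pooled z-screen at ``c1``, calibrated Fisher phase 2.

    The phase-2 cutoff for each advancing antibody is looked up in the
    calibration table at the pooled (group-count-weighted) two-arm Burrows
    prevalence estimate.  The same pooled outcomes realization feeds both
    phases — phase 2 retests the same physical pools.

    Raises
    ------
    ValueError
        If the calibration table was built for a different design
        (``alpha`` aside, mismatching ``c1``, ``k`` or arm sizes).
    """
    cases, controls = matrix.case_rows, matrix.control_rows
    expect = (cases.size, controls.size, k)
    if calibration.design_params() != expect or not np.isclose(calibration.c1, c1):
        raise ValueError(
            f"calibration table built for arms/k={calibration.design_params()}, "
            f"c1={calibration.c1}; run requires arms/k={expect}, c1={c1}"
        )
    rng = np.random.SeedSequence(seed)
    s_assign, s_pool = (int(c.generate_state(1)[0] >> 1) for c in rng.spawn(2))
    scheme = assign_pools(matrix.labels, k, seed=s_assign)
    pooled = pool_outcomes(matrix, scheme, sensitivity=sensitivity, seed=s_pool)

    ng1, ng2 = scheme.n_case_groups, scheme.n_control_groups
    x_case = pooled.group_outcomes[:ng1].sum(axis=0)
    x_control = pooled.group_outcomes[ng1:].sum(axis=0)
    p_case, p_control = _burrows_p(x_case, ng1, k), _burrows_p(x_control, ng2, k)
    _, pz = _z_pvalue(
        p_case, _burrows_var(p_case, ng1, k),
        p_control, _burrows_var(p_control, ng2, k),
    )
    advanced = pz < c1

    m = matrix.n_antibodies
    final_p = np.full(m, np.nan)
    significant = np.zeros(m, dtype=bool)
    retests = 0
    subset = np.flatnonzero(advanced)
    if subset.size:
        recon, retests = reconstruct_individuals(matrix, pooled, scheme, subset)
        a = recon[cases].sum(axis=0)
        c = recon[controls].sum(axis=0)
        fisher_p = fisher_pvalues(a, c, cases.size, controls.size)
        pooled_prev = (ng1 * p_case[subset] + ng2 * p_control[subset]) / (ng1 + ng2)
        c2 = lookup_c2(calibration, pooled_prev)
        final_p[subset] = fisher_p
        significant[subset] = fisher_p < c2

    phase1 = scheme.n_groups * m
    table = _result_table(matrix.antibody_ids, pz, advanced, final_p, significant)
    return DesignResult(
        design_name="two_phase", table=table,
        total_tests=phase1 + retests, phase1_tests=phase1, phase2_tests=retests,
        params={"alpha": calibration.alpha, "k": k, "c1": c1,
                "sensitivity": sensitivity, "seed": seed},
    )


def count_tests(result: DesignResult) -> tuple[int, int, int]:
    """Return ``(total, phase1, phase2)`` assay counts for a design run."""
    return result.total_tests, result.phase1_tests, result.phase2_tests


def write_result(result: DesignResult, prefix) -> None:
    """Write per-antibody decisions as TSV and the summary as a JSON sidecar."""
    result.table.to_csv(f"{prefix}.tsv", sep="\t", index=False)
    summary = {
        "design_name": result.design_name,
        "total_tests": result.total_tests,
        "phase1_tests": result.phase1_tests,
        "phase2_tests": result.phase2_tests,
        "params": result.params,
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def read_result(prefix) -> DesignResult:
    """Load a design run written by :func:`write_result`."""
    table = pd.read_csv(f"{prefix}.tsv", sep="\t")
    with open(f"{prefix}.json") as fh:
        summary = json.load(fh)
    return DesignResult(
        design_name=summary["design_name"], table=table,
        total_tests=summary["total_tests"], phase1_tests=summary["phase1_tests"],
        phase2_tests=summary["phase2_tests"], params=summary.get("params", {}),
    )
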