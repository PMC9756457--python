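"""Monte-Carlo calibration of the phase-2 p-value cutoff.

In the two-phase screen an antibody first passes a pooled-data z-test
(phase-1 cutoff ``c1``); those advancing are retested individually and
judged by a Fisher exact test against a prevalence-dependent cutoff ``c2``.
Because rejection requires clearing both hurdles, ``c2`` must be calibrated
so the *overall* per-antibody type-I error equals the nominal ``alpha``.

Calibration is by simulation under the null of no case-control difference:
for each prevalence on a 0.00-1.00 grid in steps of 0.01, many null
antibodies are generated (both arms i.i.d. Bernoulli at that prevalence),
the full two-phase procedure is run, and realizations that fail phase 1 are
recorded with a sentinel p-value of 1.  The cutoff ``c2`` at that prevalence
is the empirical ``alpha``-quantile of all recorded p-values — so that
rejecting whenever the phase-2 p-value falls below ``c2`` yields an
unconditional rejection rate of ``alpha``.

Grid points with prevalence above 0.4, or where too few realizations advance
to phase 2 for the quantile to be stable, fall back to the mean cutoff of the
remaining (reliable) points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import _burrows_p, _burrows_var, _z_pvalue, fisher_pvalues

__all__ = [
    "CalibrationTable",
    "calibrate_c2_at",
    "build_calibration_table",
    "lookup_c2",
    "write_calibration_csv",
    "read_calibration_csv",
]

GRID = np.round(np.arange(0, 101) / 100.0, 2)
HIGH_PREVALENCE = 0.4  # grid points above this always use the fallback cutoff


@dataclass
class CalibrationTable:
    """Prevalence-indexed phase-2 cutoffs with their provenance.

    ``c2_values`` holds the final cutoffs (fallback already applied);
    ``raw_c2`` the per-point Monte-Carlo quantiles before the fallback rule.
    """

    prevalence_grid: np.ndarray
    c2_values: np.ndarray
    advanced_counts: np.ndarray
    is_fallback: np.ndarray
    fallback_c2: float
    alpha: float
    c1: float
    n_cases: int
    n_controls: int
    k: int
    reps: int
    seed: int
    min_advanced: int
    raw_c2: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.prevalence_grid) != 101:
            raise ValueError("prevalence grid must have exactly 101 points")
        c2 = np.asarray(self.c2_values, dtype=float)
        if ((c2 < 0) | (c2 > 1)).any():
            raise ValueError("cutoffs must lie in [0, 1]")

    def design_params(self) -> tuple[int, int, int]:
        return (self.n_cases, self.n_controls, self.k)


def _alpha_quantile(pvalues: np.ndarray, alpha: float) -> float:
    """Inverse-ECDF (type-1) lower alpha-quantile."""
    ordered = np.sort(pvalues)
    idx = max(int(np.ceil(alpha * ordered.size)), 1) - 1
    return float(ordered[idx])


def _null_two_phase_pvalues(
    prevalence: float,
    c1: float,
    n_cases: int,
    n_controls: int,
    k: int,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Recorded p-values for `reps` null antibodies at a common prevalence.

    Runs pooling, the Burrows/z phase-1 screen, and (for advancing
    realizations) Fisher's exact test on reconstructed individual data;
    non-advancing realizations record the sentinel p = 1.  Pool membership
    is consecutive blocks, which is distributionally identical to random
    assignment for i.i.d. outcomes.
    """
    ng1, ng2 = n_cases // k, n_controls // k
    recorded = np.ones(reps)
    # one antibody per realization, vectorised across realizations
    case = rng.random((reps, n_cases)) < prevalence
    control = rng.random((reps, n_controls)) < prevalence
    case_pools = case.reshape(reps, ng1, k)
    control_pools = control.reshape(reps, ng2, k)
    case_pos = case_pools.any(axis=2)
    control_pos = control_pools.any(axis=2)
    x1 = case_pos.sum(axis=1)
    x2 = control_pos.sum(axis=1)
    p1, p2 = _burrows_p(x1, ng1, k), _burrows_p(x2, ng2, k)
    _, pz = _z_pvalue(p1, _burrows_var(p1, ng1, k), p2, _burrows_var(p2, ng2, k))
    advanced = pz < c1
    if advanced.any():
        idx = np.flatnonzero(advanced)
        # reconstructed positives: true positives within observed-positive pools
        a = (case_pools[idx].sum(axis=2) * case_pos[idx]).sum(axis=1)
        c = (control_pools[idx].sum(axis=2) * control_pos[idx]).sum(axis=1)
        recorded[idx] = fisher_pvalues(a, c, n_cases, n_controls)
    return recorded, int(advanced.sum())


def calibrate_c2_at(
    prevalence: float,
    c1: float,
    alpha: float,
    design_params: tuple[int, int, int],
    reps: int,
    seed,
) -> tuple[float, int]:
    """Monte-Carlo phase-2 cutoff for one prevalence value.

    Returns ``(c2, advanced_count)`` where ``c2`` is the empirical
    ``alpha``-quantile of the recorded p-values (sentinel 1 for realizations
    that did not advance) and ``advanced_count`` is how many of the ``reps``
    null realizations reached phase 2.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    n_cases, n_controls, k = design_params
    if n_cases % k or n_controls % k:
        raise ValueError("arm sizes must be divisible by the group size")
    rng = np.random.default_rng(seed)
    recorded, advanced = _null_two_phase_pvalues(
        prevalence, c1, n_cases, n_controls, k, reps, rng
    )
    return _alpha_quantile(recorded, alpha), advanced


def build_calibration_table(
    c1: float,
    alpha: float,
    design_params: tuple[int, int, int],
    reps: int,
    seed: int,
    min_advanced: int | None = None,
) -> CalibrationTable:
    """Calibrate the phase-2 cutoff over the full 0.00-1.00 prevalence grid.

    Each of the 101 grid points gets its own deterministic seed derived from
    ``(seed, grid index)``, so the table is reproducible and independent of
    execution order.  Points with prevalence above 0.4, or with fewer than
    ``min_advanced`` realizations reaching phase 2 (default: 1% of ``reps``),
    are replaced by the mean cutoff of the remaining points.
    """
    if min_advanced is None:
        min_advanced = max(1, round(0.01 * reps))
    n_cases, n_controls, k = design_params
    raw = np.empty(101)
    advanced = np.empty(101, dtype=np.int64)
    for i, prev in enumerate(GRID):
        raw[i], advanced[i] = calibrate_c2_at(
            prev, c1, alpha, design_params, reps, seed=[seed, i]
        )
    reliable = (GRID <= HIGH_PREVALENCE + 1e-12) & (advanced >= min_advanced)
    if not reliable.any():
        raise RuntimeError(
            "calibration failed: no grid point produced enough phase-2 instances"
        )
    fallback = float(raw[reliable].mean())
    c2 = np.where(reliable, raw, fallback)
    return CalibrationTable(
        prevalence_grid=GRID.copy(),
        c2_values=c2,
        advanced_counts=advanced,
        is_fallback=~reliable,
        fallback_c2=fallback,
        alpha=alpha,
        c1=c1,
        n_cases=n_cases,
        n_controls=n_controls,
        k=k,
        reps=reps,
        seed=seed,
        min_advanced=min_advanced,
        raw_c2=raw,
    )


def lookup_c2(table: CalibrationTable, prevalence_estimate) -> np.ndarray | float:
    """Cutoff at the nearest grid point (ties round down); no interpolation."""
    prev = np.asarray(prevalence_estimate, dtype=float)
    idx = np.ceil(prev * 100.0 - 0.5).astype(np.int64)
    idx = np.clip(idx, 0, 100)
    out = table.c2_values[idx]
    return float(out) if np.isscalar(prevalence_estimate) else out


_HEADER_FIELDS = ("alpha", "c1", "n_cases", "n_controls", "k", "reps", "seed",
                  "min_advanced", "fallback_c2")


def write_calibration_csv(table: CalibrationTable, path) -> None:
    """Serialise a calibration table: comment-line header block + CSV body."""
    with open(path, "w") as fh:
        for name in _HEADER_FIELDS:
            fh.write(f"# {name}={getattr(table, name)}\n")
        pd.DataFrame({
            "prevalence": table.prevalence_grid,
            "c2": table.c2_values,
            "advanced_count": table.advanced_counts,
            "is_fallback": table.is_fallback.astype(int),
        }).to_csv(fh, index=False)


def read_calibration_csv(path, expect: dict | None = None) -> CalibrationTable:
    """Load a calibration table, optionally validating header fields.

    ``expect`` maps header field names (e.g. ``alpha``, ``c1``, ``k``,
    ``n_cases``) to required values; a mismatch raises ``ValueError``.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        name, _, value = line[1:].strip().partition("=")
        header[name.strip()] = float(value)
    df = pd.read_csv(pd.io.common.StringIO("".join(lines[body_start:])))
    if expect:
        for name, value in expect.items():
            if name not in header or not np.isclose(header[name], value):
                raise ValueError(
                    f"calibration table mismatch: {name}={header.get(name)} "
                    f"but the current design requires {value}"
                )
    return CalibrationTable(
        prevalence_grid=df["prevalence"].to_numpy(),
        c2_values=df["c2"].to_numpy(),
        advanced_counts=df["advanced_count"].to_numpy(dtype=np.int64),
        is_fallback=df["is_fallback"].to_numpy(dtype=bool),
        fallback_c2=header["fallback_c2"],
        alpha=header["alpha"],
        c1=header["c1"],
        n_cases=int(header["n_cases"]),
        n_controls=int(header["n_controls"]),
        k=int(header["k"]),
        reps=int(header["reps"]),
        seed=int(header["seed"]),
        min_advanced=int(header["min_advanced"]),
    )
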