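"""Pool assignment, pooled assay outcomes, and individual-level reconstruction.

Individuals are partitioned within each study arm (cases and controls are
never mixed) into disjoint pools of exactly ``k`` members.  A pool is truly
positive for an antibody when any member is positive; the observed pooled
outcome equals the truth except that a truly positive pool may test negative
with probability ``1 - sensitivity`` (dilution error).  Specificity is perfect
throughout: a truly negative pool never tests positive.

Reconstruction mirrors the retesting step of group-testing designs: members
of observed-positive pools are assayed individually (one retest each) and
take their true outcomes; members of observed-negative pools are imputed
negative without further assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AntibodyMatrix",
    "PoolingScheme",
    "PooledResult",
    "assign_pools",
    "pool_outcomes",
    "reconstruct_individuals",
    "write_matrix_csv",
    "read_matrix_csv",
]


@dataclass
class AntibodyMatrix:
    """Binary reactivity outcomes, one row per individual, one column per antibody.

    Attributes
    ----------
    outcomes : numpy.ndarray
        Matrix of 0/1 reactivity calls, shape ``(n_individuals, n_antibodies)``.
    labels : numpy.ndarray
        Per-individual case (1) / control (0) indicator.
    antibody_ids : list of str
        Ordered antibody identifiers (column names).
    individual_ids : list of str
        Ordered individual identifiers (row names).
    """

    outcomes: np.ndarray
    labels: np.ndarray
    antibody_ids: list = field(default_factory=list)
    individual_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.outcomes.ndim != 2:
            raise ValueError("outcomes must be a 2-D matrix")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError("outcomes must be binary (0/1)")
        if self.labels.shape != (self.outcomes.shape[0],):
            raise ValueError("labels length must equal the number of individuals")
        if not ((self.labels == 1).any() and (self.labels == 0).any()):
            raise ValueError("need at least one case and one control")
        if not self.antibody_ids:
            self.antibody_ids = [f"ab{j:05d}" for j in range(self.outcomes.shape[1])]
        if not self.individual_ids:
            self.individual_ids = [f"id{i:05d}" for i in range(self.outcomes.shape[0])]
        if len(self.antibody_ids) != self.outcomes.shape[1]:
            raise ValueError("antibody_ids length mismatch")
        if len(self.individual_ids) != self.outcomes.shape[0]:
            raise ValueError("individual_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_antibodies(self) -> int:
        return self.outcomes.shape[1]

    @property
    def case_rows(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @property
    def control_rows(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)


@dataclass
class PoolingScheme:
    """Partition of each arm into disjoint pools of exactly ``k`` members.

    ``case_groups`` / ``control_groups`` are integer matrices of row indices
    into the parent matrix, shape ``(n_groups_arm, k)``.
    """

    k: int
    case_groups: np.ndarray
    control_groups: np.ndarray
    seed: int | None = None

    @property
    def n_case_groups(self) -> int:
        return self.case_groups.shape[0]

    @property
    def n_control_groups(self) -> int:
        return self.control_groups.shape[0]

    @property
    def n_groups(self) -> int:
        return self.n_case_groups + self.n_control_groups

    def stacked_groups(self) -> np.ndarray:
        """All groups, case groups first, shape ``(n_groups, k)``."""
        return np.vstack([self.case_groups, self.control_groups])

    def group_of_individual(self, n_individuals: int) -> np.ndarray:
        """Map each individual row to its stacked group index."""
        mapping = np.full(n_individuals, -1, dtype=np.int64)
        stacked = self.stacked_groups()
        for g in range(stacked.shape[0]):
            mapping[stacked[g]] = g
        return mapping


@dataclass
class PooledResult:
    """Pooled assay outcomes for every (group, antibody) combination.

    ``group_outcomes`` holds the observed pooled calls, ``truth_outcomes``
    whether each pool truly contains a positive member; they coincide when
    ``sensitivity == 1``.  Rows follow the stacked (cases-first) group order
    of the originating :class:`PoolingScheme`.
    """

    group_outcomes: np.ndarray
    truth_outcomes: np.ndarray
    sensitivity: float


def assign_pools(labels, k: int, seed: int | None = None) -> PoolingScheme:
    """Randomly partition each arm into pools of exactly ``k`` individuals.

    Each arm is independently permuted (seeded) and cut into consecutive
    blocks of ``k``.  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If either arm's size is not divisible by ``k``.
    """
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError(f"group size k={k} must be at least 1")
    rng = np.random.default_rng(seed)
    groups = {}
    for name, value in (("case", 1), ("control", 0)):
        rows = np.flatnonzero(labels == value)
        if rows.size == 0 or rows.size % k != 0:
            raise ValueError(
                f"{name} arm size {rows.size} is not divisible by group size k={k}"
            )
        groups[name] = rng.permutation(rows).reshape(-1, k)
    return PoolingScheme(k=k, case_groups=groups["case"],
                         control_groups=groups["control"], seed=seed)


def pool_outcomes(
    matrix: AntibodyMatrix,
    scheme: PoolingScheme,
    sensitivity: float = 1.0,
    seed: int | None = None,
) -> PooledResult:
    """Compute pooled assay outcomes for every pool and antibody.

    A pool's true outcome is the maximum of its members' outcomes.  With
    ``sensitivity < 1``, each truly positive pool independently tests
    positive with probability ``sensitivity`` (dilution error); truly
    negative pools always test negative.
    """
    if not 0.0 < sensitivity <= 1.0:
        raise ValueError(f"sensitivity must be in (0, 1], got {sensitivity}")
    stacked = scheme.stacked_groups()
    if stacked.max(initial=-1) >= matrix.n_individuals:
        raise ValueError("pooling scheme references rows outside the matrix")
    # (n_groups, k, n_antibodies) -> max over members
    truth = matrix.outcomes[stacked].max(axis=1).astype(np.int8)
    if sensitivity < 1.0:
        rng = np.random.default_rng(seed)
        detected = rng.random(truth.shape) < sensitivity
        observed = (truth.astype(bool) & detected).astype(np.int8)
    else:
        observed = truth.copy()
    return PooledResult(group_outcomes=observed, truth_outcomes=truth,
                        sensitivity=sensitivity)


def reconstruct_individuals(
    matrix: AntibodyMatrix,
    pooled: PooledResult,
    scheme: PoolingScheme,
    antibody_subset=None,
) -> tuple[np.ndarray, int]:
    """Rebuild individual-level data by retesting members of positive pools.

    For each antibody in ``antibody_subset`` (column indices; default all),
    members of observed-positive pools take their true outcomes, each
    contributing one retest assay; members of observed-negative pools are
    imputed 0 with no assay.

    Returns
    -------
    (reconstructed, retest_count)
        ``reconstructed`` has shape ``(n_individuals, len(subset))``;
        ``retest_count = k * (number of observed-positive pools over the
        subset, both arms)``.
    """
    if antibody_subset is None:
        subset = np.arange(matrix.n_antibodies)
    else:
        subset = np.asarray(antibody_subset, dtype=np.int64)
        if subset.size and (subset.min() < 0 or subset.max() >= matrix.n_antibodies):
            raise ValueError("antibody_subset contains out-of-range column indices")
    g_of_i = scheme.group_of_individual(matrix.n_individuals)
    pool_pos = pooled.group_outcomes[:, subset]            # (n_groups, n_subset)
    member_mask = pool_pos[g_of_i]                         # (n_individuals, n_subset)
    reconstructed = (matrix.outcomes[:, subset] * member_mask).astype(np.int8)
    retest_count = int(scheme.k * pool_pos.sum())
    return reconstructed, retest_count


def write_matrix_csv(matrix: AntibodyMatrix, path) -> None:
    """Serialise an AntibodyMatrix to CSV.

    Layout: one row per individual; columns ``individual_id``, ``label``
    (``case``/``control``), then one 0/1 column per antibody, header row
    carrying the antibody identifiers.
    """
    df = pd.DataFrame(matrix.outcomes, columns=matrix.antibody_ids)
    df.insert(0, "label", np.where(matrix.labels == 1, "case", "control"))
    df.insert(0, "individual_id", matrix.individual_ids)
    df.to_csv(path, index=False)


def read_matrix_csv(path) -> AntibodyMatrix:
    """Load an AntibodyMatrix from the CSV layout of :func:`write_matrix_csv`."""
    df = pd.read_csv(path, dtype={"individual_id": str, "label": str})
    if list(df.columns[:2]) != ["individual_id", "label"]:
        raise ValueError("matrix CSV must start with individual_id,label columns")
    labels = df["label"].map({"case": 1, "control": 0})
    if labels.isna().any():
        raise ValueError("labels must be 'case' or 'control'")
    outcomes = df.iloc[:, 2:].to_numpy(dtype=np.int8)
    return AntibodyMatrix(
        outcomes=outcomes,
        labels=labels.to_numpy(dtype=np.int8),
        antibody_ids=list(df.columns[2:]),
        individual_ids=df["individual_id"].tolist(),
    )
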