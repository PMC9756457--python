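"""Core statistical kernels for pooled-sample screening.

This module provides the Burrows bias-corrected estimator of individual-level
prevalence from pooled binary assays, its variance, the two-sample z-test used
to screen antibodies on pooled data, and a two-sided Fisher's exact test.

The Burrows estimator for ``x`` positive pools out of ``n`` pools of size ``k``
is

.. math::

    \\hat p = 1 - \\left(1 - \\frac{x}{n + v}\\right)^{1/k},
    \\qquad v = \\frac{k - 1}{2k}.

It removes most of the bias of the pooled MLE :math:`1-(1-x/n)^{1/k}` and has
smaller mean-square error for prevalences up to 0.5.  The variance expression
uses :math:`\\theta = (1-\\hat p)^k` (the probability that a pool of size ``k``
is negative); a negative evaluation, possible in extreme corners of the
formula, is clamped to zero.

All kernels have scalar dataclass-based entry points and private vectorised
counterparts (``_burrows_p``, ``_burrows_var``, ``_z_pvalue``,
``fisher_pvalues``) used by the design and calibration machinery, where tens
of thousands of antibodies are processed per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import hypergeom

__all__ = [
    "PrevalenceEstimate",
    "TwoByTwoTable",
    "burrows_estimate",
    "burrows_variance",
    "z_statistic",
    "fisher_exact_two_sided",
    "fisher_pvalues",
]

# Relative tolerance for declaring a table "as extreme as" the observed one
# under the point-probability (minlike) two-sided rule; matches the convention
# of mainstream statistical software.
_MINLIKE_RTOL = 1.0 + 1e-7


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Burrows estimate of individual prevalence from pooled assay counts.

    Attributes
    ----------
    p_hat : float
        Bias-corrected prevalence estimate, in ``[0, 1)``.
    x : int
        Number of positive pools.
    n : int
        Total number of pools.
    k : int
        Pool size (individuals per pool).
    v : float
        Bias-correction constant ``(k - 1) / (2 k)``.
    variance : float
        Estimated variance of ``p_hat`` (zero when ``x == 0``).
    """

    p_hat: float
    x: int
    n: int
    k: int
    v: float
    variance: float

    @property
    def theta(self) -> float:
        """Probability that a pool tests negative, ``(1 - p_hat) ** k``."""
        return (1.0 - self.p_hat) ** self.k


@dataclass(frozen=True)
class TwoByTwoTable:
    """A 2x2 contingency table of case/control positivity counts.

    ``a``/``b`` are case positives/negatives, ``c``/``d`` control
    positives/negatives.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ValueError(f"table entry {name}={value} must be a nonnegative integer")


def _burrows_p(x, n: int, k: int):
    """Vectorised Burrows point estimate; ``x`` may be an array."""
    v = (k - 1) / (2.0 * k)
    return 1.0 - (1.0 - np.asarray(x, dtype=float) / (n + v)) ** (1.0 / k)


def _burrows_var(p_hat, n: int, k: int):
    """Vectorised Burrows variance with theta = (1-p)^k, clamped at zero.

    The second (subtracted) term is a squared bracket; it is O(1/n^4) and
    numerically negligible but retained for fidelity to the estimator's
    published form.
    """
    p = np.asarray(p_hat, dtype=float)
    v = (k - 1) / (2.0 * k)
    theta = (1.0 - p) ** k
    with np.errstate(divide="ignore", invalid="ignore"):
        lead = (1.0 - theta) * (1.0 - p) ** 2 / k**2
        inner = 1.0 / (n * theta) + 2.0 * (1.0 - theta) * v**2 / (n * theta) ** 2
        second = (
            v * (1.0 - 2.0 * v) * (1.0 - theta) * (1.0 - p) * (1.0 + theta) * (1.0 - v)
            / (6.0 * n**2 * theta**2)
        ) ** 2
        var = lead * inner - second
    var = np.where(theta > 0.0, var, np.nan)
    return np.clip(var, 0.0, None)


def burrows_estimate(x: int, n: int, k: int) -> PrevalenceEstimate:
    """Estimate individual-level prevalence from pooled assay outcomes.

    Parameters
    ----------
    x : int
        Number of positive pools, ``0 <= x <= n``.
    n : int
        Number of pools, at least 1.
    k : int
        Pool size, at least 1.  ``k == 1`` reduces exactly to the binomial
        proportion ``x / n``.

    Returns
    -------
    PrevalenceEstimate
        Point estimate with its variance attached.
    """
    if n < 1 or k < 1:
        raise ValueError(f"n and k must be positive (got n={n}, k={k})")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} must satisfy 0 <= x <= n={n}")
    v = (k - 1) / (2.0 * k)
    p_hat = float(_burrows_p(x, n, k))
    # p_hat = 1 only at x = n with k = 1 (no bias correction); the estimate is
    # then degenerate and its variance is taken as 0
    variance = 0.0 if p_hat >= 1.0 else float(_burrows_var(p_hat, n, k))
    return PrevalenceEstimate(p_hat=p_hat, x=int(x), n=int(n), k=int(k), v=v, variance=variance)


def burrows_variance(est: PrevalenceEstimate) -> float:
    """Variance of a Burrows prevalence estimate.

    Raises
    ------
    ValueError
        If ``p_hat == 1`` (``theta == 0``), where the variance is undefined.
    """
    if est.p_hat >= 1.0:
        raise ValueError("variance undefined for p_hat = 1 (theta = 0)")
    return float(_burrows_var(est.p_hat, est.n, est.k))


def _z_pvalue(p_case, var_case, p_control, var_control):
    """Vectorised two-sided z-test of equal prevalence on pooled estimates.

    Both-variances-zero cells (possible only when both arms had zero positive
    pools, hence equal estimates) are defined as z=0, p=1.
    """
    p_case = np.asarray(p_case, dtype=float)
    p_control = np.asarray(p_control, dtype=float)
    denom = np.sqrt(np.asarray(var_case, dtype=float) + np.asarray(var_control, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0.0, (p_case - p_control) / np.where(denom > 0, denom, 1.0), 0.0)
    pval = 2.0 * ndtr(-np.abs(z))
    return z, np.minimum(pval, 1.0)


def z_statistic(case: PrevalenceEstimate, control: PrevalenceEstimate) -> tuple[float, float]:
    """Two-sided z-test comparing case and control pooled prevalence estimates.

    Returns ``(z, p_value)`` with
    ``z = (p_case - p_control) / sqrt(var_case + var_control)``.  When both
    variances are zero (no positive pool in either arm) the comparison is
    defined as non-significant: ``(0.0, 1.0)``.
    """
    if case.variance == 0.0 and control.variance == 0.0:
        if case.p_hat != control.p_hat:
            raise RuntimeError(
                "internal inconsistency: zero variances with unequal estimates"
            )
        return 0.0, 1.0
    z, p = _z_pvalue(case.p_hat, case.variance, control.p_hat, control.variance)
    return float(z), float(p)


def _fisher_one(a: int, c: int, n1: int, n2: int) -> float:
    """Two-sided (minlike) Fisher exact p-value for one table with fixed margins.

    ``a`` positives among ``n1`` cases, ``c`` positives among ``n2`` controls.
    Degenerate margins (an all-zero or all-one row/column) return 1.
    """
    m = a + c
    if n1 == 0 or n2 == 0 or m == 0 or m == n1 + n2:
        return 1.0
    lo = max(0, m - n2)
    hi = min(m, n1)
    if lo == hi:
        return 1.0
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n1 + n2, m, n1)
    observed = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= observed * _MINLIKE_RTOL].sum()))


# Cache of computed p-values keyed by (a, c, n1, n2).  The screening designs
# evaluate many antibodies against the same fixed arm sizes, so hit rates
# approach 100% after the first replicate.
_fisher_cache: dict[tuple[int, int, int, int], float] = {}


def fisher_pvalues(a, c, n1: int, n2: int) -> np.ndarray:
    """Two-sided Fisher exact p-values for many tables sharing margins.

    Parameters
    ----------
    a, c : array-like of int
        Positives among cases (out of ``n1``) and controls (out of ``n2``),
        one entry per table.

    Returns
    -------
    numpy.ndarray
        P-values, same shape as ``a``.
    """
    a = np.asarray(a, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    out = np.empty(a.shape, dtype=float)
    flat_a, flat_c, flat_out = a.ravel(), c.ravel(), out.ravel()
    for i in range(flat_a.size):
        key = (int(flat_a[i]), int(flat_c[i]), n1, n2)
        p = _fisher_cache.get(key)
        if p is None:
            p = _fisher_one(key[0], key[1], n1, n2)
            _fisher_cache[key] = p
        flat_out[i] = p
    return out


def fisher_exact_two_sided(table: TwoByTwoTable) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Uses the point-probability ("minlike") rule: the p-value is the total
    hypergeometric probability of all tables with the observed margins whose
    probability does not exceed that of the observed table.  Tables with an
    empty margin return 1.
    """
    n1 = table.a + table.b
    n2 = table.c + table.d
    return _fisher_one(table.a, table.c, n1, n2)
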