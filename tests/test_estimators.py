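"""Unit and property tests for the pooled-prevalence and exact-test kernels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact, hypergeom, norm

from poolscreen import (
    PrevalenceEstimate,
    TwoByTwoTable,
    burrows_estimate,
    burrows_variance,
    fisher_exact_two_sided,
    fisher_pvalues,
    z_statistic,
)
from poolscreen.estimators import _burrows_p, _burrows_var, _z_pvalue


class TestBurrowsEstimate:
    def test_zero_positive_pools_gives_zero(self):
        est = burrows_estimate(0, 100, 5)
        assert est.p_hat == 0.0
        assert est.variance == 0.0

    def test_k1_is_binomial_proportion_exhaustive(self):
        # with a single-member pool there is no pooling bias to correct
        for n in (1, 7, 50):
            for x in range(n + 1):
                assert burrows_estimate(x, n, 1).p_hat == pytest.approx(x / n, abs=1e-12)

    def test_printed_formula_example(self):
        # independent arithmetic: v=0.4, p = 1-(1-40/100.4)^(1/5)
        est = burrows_estimate(40, 100, 5)
        assert est.v == pytest.approx(0.4)
        assert est.p_hat == pytest.approx(0.09664043952641221, rel=1e-12)

    def test_strictly_increasing_in_x(self):
        p = _burrows_p(np.arange(0, 101), 100, 5)
        assert (np.diff(p) > 0).all()
        assert p[0] == 0.0 and p[-1] < 1.0

    @given(st.integers(1, 30), st.integers(1, 10), st.data())
    @settings(max_examples=50, deadline=None)
    def test_estimate_bounds(self, n, k, data):
        x = data.draw(st.integers(0, n))
        est = burrows_estimate(x, n, k)
        assert 0.0 <= est.p_hat <= 1.0
        if k >= 2:  # the bias correction keeps pooled estimates below 1
            assert est.p_hat < 1.0
        assert est.v == pytest.approx((k - 1) / (2 * k))

    @pytest.mark.parametrize("x,n,k", [(5, 4, 5), (0, 0, 5), (1, 10, 0), (-1, 10, 5)])
    def test_invalid_inputs_raise(self, x, n, k):
        with pytest.raises(ValueError):
            burrows_estimate(x, n, k)


class TestBurrowsVariance:
    def test_matches_direct_arithmetic(self):
        # evaluated term by term with explicit floats, independent of the kernel
        x, n, k = 40, 100, 5
        v = 0.4
        p = 1 - (1 - x / (n + v)) ** (1 / k)
        theta = (1 - p) ** k
        lead = (1 - theta) * (1 - p) ** 2 / k**2 * (1 / (n * theta) + 2 * (1 - theta) * v**2 / (n * theta) ** 2)
        second = (v * (1 - 2 * v) * (1 - theta) * (1 - p) * (1 + theta) * (1 - v) / (6 * n**2 * theta**2)) ** 2
        expected = lead - second
        assert expected == pytest.approx(0.00021663255228014983, rel=1e-10)
        assert burrows_variance(burrows_estimate(x, n, k)) == pytest.approx(expected, rel=1e-12)

    def test_decreases_with_more_pools(self):
        # leading term scales as 1/n at fixed prevalence and pool size
        p_fixed = 0.1
        v100 = float(_burrows_var(p_fixed, 100, 5))
        v200 = float(_burrows_var(p_fixed, 200, 5))
        assert v200 < v100
        assert float(_burrows_var(p_fixed, 100_000, 5)) < 1e-6

    def test_undefined_at_saturation(self):
        est = PrevalenceEstimate(p_hat=1.0, x=10, n=10, k=1, v=0.0, variance=0.0)
        with pytest.raises(ValueError):
            burrows_variance(est)

    def test_never_negative(self):
        for n in (4, 20, 100):
            p = _burrows_p(np.arange(0, n + 1), n, 5)
            assert (_burrows_var(p, n, 5) >= 0).all()


class TestBurrowsBias:
    def test_less_biased_than_mle(self):
        """Monte-Carlo: |bias of Burrows| <= |bias of the pooled MLE| for p <= 0.5."""
        rng = np.random.default_rng(2718)
        n, k, reps = 100, 5, 20_000
        for p in (0.05, 0.1, 0.3, 0.5):
            theta = 1 - (1 - p) ** k
            x = rng.binomial(n, theta, size=reps)
            burrows = _burrows_p(x, n, k)
            mle = 1 - (1 - x / n) ** (1 / k)
            assert abs(burrows.mean() - p) <= abs(mle.mean() - p)


class TestZStatistic:
    def test_identical_estimates_give_null(self):
        est = burrows_estimate(30, 100, 5)
        z, p = z_statistic(est, est)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = burrows_estimate(40, 100, 5), burrows_estimate(25, 100, 5)
        z1, p1 = z_statistic(a, b)
        z2, p2 = z_statistic(b, a)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_hand_computed_example(self):
        case = PrevalenceEstimate(0.15, 0, 0, 1, 0.0, 0.0004)
        control = PrevalenceEstimate(0.10, 0, 0, 1, 0.0, 0.0004)
        z, p = z_statistic(case, control)
        assert z == pytest.approx(0.05 / np.sqrt(0.0008), rel=1e-9)
        assert p == pytest.approx(0.0771, abs=2e-4)

    def test_degenerate_both_zero(self):
        zero = burrows_estimate(0, 100, 5)
        assert z_statistic(zero, zero) == (0.0, 1.0)

    def test_near_nominal_type1_under_simulated_null(self):
        """Pooled z-test on two equal-prevalence arms rejects near alpha."""
        rng = np.random.default_rng(99)
        n, k, reps, prev, alpha = 100, 5, 40_000, 0.1, 0.05
        x1 = (rng.random((reps, n, k)) < prev).any(axis=2).sum(axis=1)
        x2 = (rng.random((reps, n, k)) < prev).any(axis=2).sum(axis=1)
        p1, p2 = _burrows_p(x1, n, k), _burrows_p(x2, n, k)
        _, pz = _z_pvalue(p1, _burrows_var(p1, n, k), p2, _burrows_var(p2, n, k))
        rate = (pz < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se + 0.01  # small discreteness allowance


def _enumeration_pvalue(a, b, c, d):
    """Brute-force minlike two-sided p: enumerate all tables with the margins."""
    n1, n2, m = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or m == 0 or m == n1 + n2:
        return 1.0
    support = range(max(0, m - n2), min(m, n1) + 1)
    probs = {i: hypergeom.pmf(i, n1 + n2, m, n1) for i in support}
    obs = probs[a]
    return min(1.0, sum(q for q in probs.values() if q <= obs * (1 + 1e-7)))


class TestFisherExact:
    def test_extreme_table(self):
        # margins (5,5,5,5): only the observed and its mirror are as extreme
        assert fisher_exact_two_sided(TwoByTwoTable(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_mode_table_and_degenerate_column(self):
        assert fisher_exact_two_sided(TwoByTwoTable(3, 7, 3, 7)) == pytest.approx(1.0)
        assert fisher_exact_two_sided(TwoByTwoTable(0, 10, 0, 10)) == 1.0

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n1, n2 = rng.integers(1, 60, size=2)
            a, c = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            mine = fisher_exact_two_sided(TwoByTwoTable(int(a), int(n1 - a), int(c), int(n2 - c)))
            ref = fisher_exact([[a, n1 - a], [c, n2 - c]])[1]
            assert mine == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_matches_enumeration_small_margins(self):
        # spot-check of the exhaustive acceptance property at small margins
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        table = TwoByTwoTable(a, n1 - a, c, n2 - c)
                        assert fisher_exact_two_sided(table) == pytest.approx(
                            _enumeration_pvalue(a, n1 - a, c, n2 - c), rel=1e-9
                        )

    def test_vectorised_path_matches_scalar(self):
        a = np.array([0, 3, 7, 12])
        c = np.array([5, 3, 1, 0])
        vec = fisher_pvalues(a, c, 15, 12)
        for i in range(a.size):
            tab = TwoByTwoTable(int(a[i]), 15 - int(a[i]), int(c[i]), 12 - int(c[i]))
            assert vec[i] == pytest.approx(fisher_exact_two_sided(tab))

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)
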