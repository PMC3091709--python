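"""Chi-squared battery, FDR, envelopes, bootstrap, KS."""

import numpy as np
import pytest
from scipy import stats as sps

from ssrrep import repstats
from ssrrep.repstats import (
    CHI2_DF1_CRIT,
    bh_adjust,
    binom_two_sided,
    bootstrap_chromosome_stat,
    cell_tests,
    chi2_gof,
    chi2_independence,
    expected_envelope,
    fraction_below,
    global_gof,
    ks_two_sample,
    mc_null_pvalue,
    restrict_to_support,
)


class TestChi2Gof:
    def test_exact_fit(self):
        res = chi2_gof([25, 25, 25, 25], [0.25] * 4)
        assert res.statistic == 0 and res.p_asymptotic == 1

    def test_closed_forms(self):
        res = chi2_gof([60, 40], [0.5, 0.5])
        assert res.statistic == pytest.approx(4.0) and res.df == 1
        res = chi2_gof([10, 20, 30, 40], [0.25] * 4)
        assert res.statistic == pytest.approx(20.0) and res.df == 3

    def test_incompatible_flag(self):
        res = chi2_gof([5, 5, 1], [0.5, 0.5, 0.0])
        assert res.method == "gof-incompatible" and np.isinf(res.statistic)

    def test_zero_probability_cells_excluded_from_df(self):
        res = chi2_gof([5, 5, 0], [0.5, 0.5, 0.0])
        assert res.df == 1

    def test_matches_scipy(self, rng):
        for _ in range(25):
            k = int(rng.integers(3, 12))
            p = rng.dirichlet(np.ones(k))
            obs = rng.multinomial(500, p)
            mine = chi2_gof(obs, p)
            ref = sps.chisquare(obs, 500 * p)
            assert mine.statistic == pytest.approx(ref.statistic)
            assert mine.p_asymptotic == pytest.approx(ref.pvalue)


class TestChi2Independence:
    def test_exact_independence(self):
        assert chi2_independence([[10, 10], [10, 10]]).statistic == 0

    def test_diagonal_table(self):
        res = chi2_independence([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0) and res.df == 1

    def test_degenerate(self):
        with pytest.raises(ValueError):
            chi2_independence([[5, 5]])
        with pytest.raises(ValueError):
            chi2_independence([[5, 5], [0, 0]])

    def test_matches_scipy(self, rng):
        for _ in range(25):
            t = rng.integers(1, 40, size=(3, 4))
            mine = chi2_independence(t)
            stat, p, df, _ = sps.chi2_contingency(t, correction=False)
            assert mine.statistic == pytest.approx(stat)
            assert mine.df == df and mine.p_asymptotic == pytest.approx(p)


class TestMonteCarlo:
    def test_zero_statistic_gives_p_one(self):
        res = mc_null_pvalue([25, 25, 25, 25], [0.25] * 4, B=199, seed=1)
        assert res.p_montecarlo == 1.0

    def test_matches_exact_binomial_tail(self):
        # chi2 >= 4.0 for O=[x, 100-x] vs p=0.5 iff |x - 50| >= 10; the exact
        # null tail is 2 P(X >= 60), slightly above the asymptotic 0.0455
        res = mc_null_pvalue([60, 40], [0.5, 0.5], B=9999, seed=2)
        exact = 2 * sps.binom.sf(59, 100, 0.5)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.p_montecarlo - exact) < 3 * se

    def test_deterministic_and_requires_seed(self):
        a = mc_null_pvalue([30, 20, 10], [0.4, 0.4, 0.2], B=299, seed=7)
        b = mc_null_pvalue([30, 20, 10], [0.4, 0.4, 0.2], B=299, seed=7)
        assert a.p_montecarlo == b.p_montecarlo
        with pytest.raises(ValueError):
            mc_null_pvalue([10, 10], [0.5, 0.5], B=299)
        with pytest.raises(ValueError):
            mc_null_pvalue([10, 10], [0.5, 0.5], B=50, seed=1)

    def test_category_permutation_invariance(self, rng):
        obs = np.array([40, 25, 15, 20])
        p = np.array([0.3, 0.3, 0.2, 0.2])
        perm = rng.permutation(4)
        a = mc_null_pvalue(obs, p, B=999, seed=3)
        b = mc_null_pvalue(obs[perm], p[perm], B=999, seed=3)
        assert a.p_montecarlo == b.p_montecarlo

    def test_independence_mode_null(self):
        t = [[50, 50], [50, 50]]
        res = mc_null_pvalue(t, independence=True, B=199, seed=4)
        assert res.p_montecarlo == 1.0
        skewed = mc_null_pvalue([[40, 5], [5, 40]], independence=True, B=999, seed=5)
        assert skewed.p_montecarlo < 0.01

    def test_global_gof_trigger(self):
        # all expected counts >= 5: asymptotic route, no MC field
        big = global_gof([100, 100], [0.5, 0.5])
        assert big.p_montecarlo is None
        small = global_gof([3, 2, 1] + [1] * 3, [1 / 6] * 6, B=199, seed=6)
        assert small.p_montecarlo is not None


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
            ([0.3], [0.3]),
        ],
    )
    def test_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(10):
            p = rng.uniform(size=30)
            ref = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(ref)


class TestBinomTwoSided:
    def test_matches_scipy_binomtest(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 2000))
            p = float(rng.uniform(0.001, 0.999))
            k = int(rng.integers(0, n + 1))
            assert binom_two_sided(k, n, p)[0] == pytest.approx(
                sps.binomtest(k, n, p).pvalue, rel=1e-9, abs=1e-300
            )

    def test_degenerate_probabilities(self):
        assert binom_two_sided(0, 10, 0.0)[0] == 1.0
        assert binom_two_sided(1, 10, 0.0)[0] > 0  # minimal positive value
        assert binom_two_sided(10, 10, 1.0)[0] == 1.0


class TestCellTests:
    def test_exact_expectation_all_none(self):
        obs = np.array([25, 25, 25, 25])
        cells = cell_tests(obs, np.full(4, 0.25))
        assert all(c.direction == "none" for c in cells)

    def test_gross_excess_flagged_over(self):
        p = np.full(100, 0.01)
        obs = np.full(100, 9)
        obs[0] = 100  # n = 991, cell 0 at ~10x its expectation
        cells = cell_tests(obs, p)
        assert cells[0].direction == "over" and cells[0].p_adjusted < 0.05
        # binomial tail oracle on the raw p-value
        assert cells[0].p_raw == pytest.approx(
            sps.binomtest(100, int(obs.sum()), 0.01).pvalue
        )

    def test_directions_follow_sign(self):
        obs = np.array([80, 20])
        cells = cell_tests(obs, np.array([0.5, 0.5]))
        assert cells[0].direction == "over" and cells[1].direction == "under"
        flipped = cell_tests(obs[::-1], np.array([0.5, 0.5]))
        assert flipped[0].direction == "under" and flipped[1].direction == "over"

    def test_ztest_variant_agrees_on_gross_effects(self):
        obs = np.array([80, 20])
        z = cell_tests(obs, np.array([0.5, 0.5]), method="ztest")
        assert z[0].direction == "over"


class TestEnvelope:
    def test_degenerate(self):
        lo, hi = expected_envelope(50, [1.0, 0.0])
        assert (lo[0], hi[0]) == (50, 50) and (lo[1], hi[1]) == (0, 0)

    def test_matches_cdf_enumeration(self):
        lo, hi = expected_envelope(100, [0.5])
        cdf = np.cumsum([sps.binom.pmf(k, 100, 0.5) for k in range(101)])
        lo_ref = int(np.searchsorted(cdf, 0.025))
        hi_ref = int(np.searchsorted(cdf, 0.975))
        assert lo[0] == lo_ref and hi[0] == hi_ref

    def test_validation(self):
        with pytest.raises(ValueError):
            expected_envelope(0, [0.5])
        with pytest.raises(ValueError):
            expected_envelope(10, [0.5], level=1.0)


class TestBootstrap:
    def test_identical_rows_zero_width(self):
        table = np.tile([5, 10, 20, 5], (2, 1))
        ci = bootstrap_chromosome_stat(table, 2, n_boot=50, seed=1)
        assert ci.lower == ci.upper == 0.0

    def test_deterministic(self, rng):
        table = rng.integers(0, 30, size=(5, 10))
        a = bootstrap_chromosome_stat(table, 3, n_boot=100, seed=9)
        b = bootstrap_chromosome_stat(table, 3, n_boot=100, seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert a.lower <= a.upper

    def test_reference_mode(self, rng):
        obs = rng.integers(1, 30, size=(4, 10)).astype(float)
        ci = bootstrap_chromosome_stat(
            obs, 3, n_boot=100, seed=2, mode="reference", reference=obs
        )
        assert ci.lower == ci.upper == 0.0  # observed equals reference exactly

    def test_validation(self):
        table = np.ones((3, 10))
        with pytest.raises(ValueError):
            bootstrap_chromosome_stat(table, 1, seed=1)
        with pytest.raises(ValueError):
            bootstrap_chromosome_stat(table, 4, seed=1)
        with pytest.raises(ValueError):
            bootstrap_chromosome_stat(table, 2)


class TestKSAndFractions:
    def test_ks_examples(self):
        assert ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0
        assert ks_two_sample([1, 2, 3], [4, 5, 6])[0] == 1.0
        assert ks_two_sample([1, 2], [1.5])[0] == 0.5

    def test_ks_symmetry(self, rng):
        a, b = rng.normal(size=40), rng.normal(0.5, 1.2, size=30)
        assert ks_two_sample(a, b) == ks_two_sample(b, a)
        d, _ = ks_two_sample(a, b)
        assert 0 <= d <= 1
        with pytest.raises(ValueError):
            ks_two_sample([], [1])

    def test_fraction_below(self):
        assert fraction_below([1, 2, 5], 3.84) == pytest.approx(2 / 3)
        assert fraction_below([0.1, 0.2]) == 1.0
        assert round(CHI2_DF1_CRIT, 2) == 3.84
        with pytest.raises(ValueError):
            fraction_below([])


def test_restrict_to_support():
    obs, p, outside = restrict_to_support([5, 3, 2], [0.5, 0.5, 0.0])
    assert list(obs) == [5, 3] and outside == 2
    assert p.sum() == pytest.approx(1.0)


def test_mc_and_asymptotic_agree_when_expected_large(rng):
    """With expected counts >= 5 the two p-value routes coincide."""
    p = rng.dirichlet(np.ones(8) * 5)
    obs = rng.multinomial(2000, p)
    res = mc_null_pvalue(obs, p, B=4999, seed=11)
    se = np.sqrt(max(res.p_asymptotic * (1 - res.p_asymptotic), 1e-4) / 4999)
    assert abs(res.p_montecarlo - res.p_asymptotic) < 4 * se + 1e-3
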