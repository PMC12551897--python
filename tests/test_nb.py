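"""Negative binomial marginals, quantile transform, and Z-tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cctcount.copulas import CopulaSpec, sample_copula
from cctcount.nb import (
    NegBinParams,
    counts_from_copula,
    nb_cdf_table,
    nb_moments,
    nb_pmf,
    nb_quantile,
    standardized_skewness,
    z_test,
)


class TestParams:
    @pytest.mark.parametrize("r, p", [(0.0, 0.5), (-1.0, 0.5), (1.0, 0.0), (1.0, 1.0)])
    def test_invalid_rejected(self, r, p):
        with pytest.raises(ValueError):
            NegBinParams(r, p)

    @pytest.mark.parametrize(
        "r, p, mean, var",
        [(10, 0.5, 10, 20), (30, 0.5, 30, 60), (11, 0.5, 11, 22), (5, 0.25, 15, 60)],
    )
    def test_moments(self, r, p, mean, var):
        assert nb_moments(NegBinParams(r, p)) == pytest.approx((mean, var))
        # overdispersion: variance always exceeds the mean for p < 1
        assert var > mean


class TestPmf:
    @pytest.mark.parametrize(
        "r, p, x, expected",
        [(1, 0.5, 0, 0.5), (2, 0.5, 1, 0.25), (1, 0.5, 3, 0.0625)],
    )
    def test_known_values(self, r, p, x, expected):
        assert nb_pmf(NegBinParams(r, p), x) == pytest.approx(expected, abs=1e-14)

    def test_normalization(self):
        params = NegBinParams(10, 0.5)
        total = nb_pmf(params, np.arange(501)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_non_integer_r_allowed(self):
        # gamma-function binomial coefficient
        val = nb_pmf(NegBinParams(2.5, 0.4), 3)
        assert 0.0 < val < 1.0

    @pytest.mark.parametrize("x", [-1, 0.5])
    def test_invalid_x_rejected(self, x):
        with pytest.raises(ValueError):
            nb_pmf(NegBinParams(2, 0.5), x)


class TestQuantile:
    def test_known_values(self):
        assert nb_quantile(NegBinParams(1, 0.5), 0.5) == 0
        assert nb_quantile(NegBinParams(10, 0.5), 1e-12) == 0

    def test_matches_linear_scan_oracle(self):
        params = NegBinParams(10, 0.5)
        for u in (0.3, 0.72, 0.999999):
            cdf = 0.0
            x = 0
            while True:
                cdf += nb_pmf(params, x)
                if cdf >= u:
                    break
                x += 1
            assert nb_quantile(params, u) == x

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_u_rejected(self, u):
        with pytest.raises(ValueError):
            nb_quantile(NegBinParams(2, 0.5), u)

    @given(
        st.floats(1e-9, 1 - 1e-9),
        st.floats(0.5, 60.0),
        st.floats(0.1, 0.9),
    )
    @settings(max_examples=200, deadline=None)
    def test_cdf_adjunction(self, u, r, p):
        """nb_quantile is the left-continuous generalized inverse:
        CDF(q(u)) >= u and CDF(q(u) - 1) < u."""
        params = NegBinParams(r, p)
        x = nb_quantile(params, u)
        assert stats.nbinom.cdf(x, r, p) >= u
        if x > 0:
            assert stats.nbinom.cdf(x - 1, r, p) < u

    def test_table_lookup_equals_scipy_ppf(self):
        """The vectorized searchsorted path agrees with scipy's ppf."""
        rng = np.random.default_rng(5)
        u = rng.uniform(1e-9, 1 - 1e-9, size=2000)
        for r, p in [(5, 0.5), (30, 0.5), (2.5, 0.3)]:
            params = NegBinParams(r, p)
            table = nb_cdf_table(params)
            via_table = np.searchsorted(table, u, side="left")
            via_ppf = stats.nbinom.ppf(u, r, p).astype(int)
            np.testing.assert_array_equal(via_table, via_ppf)


class TestCountsFromCopula:
    def test_dimension_mismatch_rejected(self):
        u = np.full((5, 3), 0.5)
        with pytest.raises(ValueError, match="columns"):
            counts_from_copula(u, [NegBinParams(2, 0.5)] * 2)

    def test_comonotone_uniforms_give_identical_columns(self):
        col = np.linspace(0.05, 0.95, 40)
        u = np.column_stack([col, col])
        counts = counts_from_copula(u, [NegBinParams(10, 0.5)] * 2)
        np.testing.assert_array_equal(counts[:, 0], counts[:, 1])

    def test_moment_recovery_under_independence(self):
        n = 100_000
        u = sample_copula(CopulaSpec("independence", dim=1), n, seed=99)
        counts = counts_from_copula(u, [NegBinParams(10, 0.5)])
        mean, var = counts.mean(), counts.var(ddof=1)
        # 3-sigma CLT bands around the theoretical moments (10, 20)
        assert abs(mean - 10) < 3 * np.sqrt(20 / n)
        se_var = np.sqrt(2 / (n - 1)) * 20 * 2  # generous band for the variance
        assert abs(var - 20) < 3 * se_var

    def test_concordance_preserved_from_clayton(self):
        u = sample_copula(CopulaSpec("clayton", 5.0, dim=2), 5000, seed=17)
        counts = counts_from_copula(u, [NegBinParams(10, 0.5)] * 2)
        tau, _ = stats.kendalltau(counts[:, 0], counts[:, 1])
        assert tau > 0.5

    def test_counts_are_non_negative_integers(self):
        u = sample_copula(CopulaSpec("gumbel", 2.0, dim=3), 200, seed=1)
        counts = counts_from_copula(u, [NegBinParams(5, 0.5)] * 3)
        assert counts.dtype == np.int64
        assert np.all(counts >= 0)


class TestZTest:
    def test_zero_when_mean_equals_null(self):
        res = z_test(np.full(20, 7.0), null_mean=7.0, null_variance=4.0)
        assert res.z == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_critical_value(self):
        n, var = 25, 9.0
        shift = 1.959964 * np.sqrt(var / n)
        data = np.full(n, 3.0) + shift
        res = z_test(data, null_mean=3.0, null_variance=var)
        assert res.p_value[0] == pytest.approx(0.05, abs=1e-4)

    def test_two_sided_identity(self):
        rng = np.random.default_rng(0)
        data = rng.poisson(5, size=(40, 3))
        res = z_test(data, null_mean=5.0, null_variance=5.0)
        expected = 2 * (1 - stats.norm.cdf(np.abs(res.z)))
        np.testing.assert_allclose(res.p_value, expected, atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.normal(10, 2, size=50)
        base = z_test(data, null_mean=10.0, null_variance=4.0)
        shifted = z_test(data + 3.0, null_mean=13.0, null_variance=4.0)
        assert base.p_value[0] == pytest.approx(shifted.p_value[0], abs=1e-12)

    def test_null_pvalues_approximately_uniform(self):
        """Under H0 with r = 30, n = 30, the Z-test p-value distribution
        over 10,000 replicates is close to uniform (KS distance < 0.02)."""
        rng = np.random.default_rng(123)
        M, n, r = 10_000, 30, 30
        counts = rng.negative_binomial(r, 0.5, size=(M, n))
        res = z_test(counts.T, null_mean=30.0, null_variance=60.0)
        ks = stats.kstest(res.p_value, "uniform").statistic
        assert ks < 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            z_test(np.array([1.0]), null_mean=0.0, null_variance=0.0)
        with pytest.raises(ValueError):
            z_test(np.array([[1.0]]), null_mean=0.0, null_variance=1.0, n=0)


class TestStandardizedSkewness:
    @pytest.mark.parametrize(
        "r, n, expected",
        [(5, 30, 0.17), (10, 30, 0.12), (50, 30, 0.05), (20, 100, 0.05), (5, 200, 0.07)],
    )
    def test_guideline_table_values(self, r, n, expected):
        got = standardized_skewness(NegBinParams(r, 0.5), n)
        assert round(got, 2) == expected

    def test_strictly_decreasing_in_r_and_n(self):
        vals_r = [standardized_skewness(NegBinParams(r, 0.5), 30) for r in range(5, 100, 5)]
        assert all(a > b for a, b in zip(vals_r, vals_r[1:]))
        vals_n = [standardized_skewness(NegBinParams(10, 0.5), n) for n in (5, 30, 100, 500)]
        assert all(a > b for a, b in zip(vals_n, vals_n[1:]))

    def test_vanishes_for_large_r(self):
        assert standardized_skewness(NegBinParams(1e8, 0.5), 30) < 1e-3
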