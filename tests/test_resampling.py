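"""Inverse-CDF resampling and empirical p-values."""

import numpy as np
import pytest

import betarank as br
from betarank.resample import DegenerateCdfError


class TestFittedCdf:
    def test_endpoint_inverse(self):
        cdf = br.fitted_rank_to_cdf(np.array([8.0, 4.0, 2.0]), 3)
        assert cdf.inverse(1 / 3) == pytest.approx(8.0)
        assert cdf.inverse(1.0) == pytest.approx(2.0)
        assert cdf.inverse(0.01) == pytest.approx(8.0)  # clamp below the grid

    def test_inverse_monotone(self):
        fitted = 100.0 / np.arange(1, 51) ** 0.5
        cdf = br.fitted_rank_to_cdf(fitted, 50)
        grid = np.linspace(0.01, 0.99, 99)
        vals = cdf.inverse(grid)
        assert np.all(np.diff(vals) <= 0)

    def test_round_trip_on_interior_grid(self):
        fitted = 100.0 / np.arange(1, 51) ** 0.5
        cdf = br.fitted_rank_to_cdf(fitted, 50)
        grid = np.linspace(1 / 50, 1.0, 40)
        assert np.allclose(cdf.cum_prob_at(cdf.inverse(grid)), grid, atol=1e-12)

    def test_non_monotone_fitted_rejected(self):
        with pytest.raises(ValueError):
            br.fitted_rank_to_cdf(np.array([5.0, 6.0, 2.0]), 3)

    def test_from_fit_results(self, zipf_ranked):
        res = br.ZipfRankModel(zipf_ranked).fit()
        cdf = br.fitted_rank_to_cdf(res)
        assert cdf.support.size == zipf_ranked.n_F


class TestSampling:
    @pytest.fixture
    def zipf_cdf(self):
        fitted = 10 ** 2.3 / np.arange(1, 501) ** 0.5
        return br.fitted_rank_to_cdf(fitted, 500)

    def test_deterministic_under_seed(self, zipf_cdf):
        s1 = br.sample_sizes_from_cdf(zipf_cdf, 200, rng_seed=42, min_size=2)
        s2 = br.sample_sizes_from_cdf(zipf_cdf, 200, rng_seed=42, min_size=2)
        assert np.array_equal(s1.sizes, s2.sizes)

    def test_min_size_filter(self, zipf_cdf):
        s = br.sample_sizes_from_cdf(zipf_cdf, 500, rng_seed=1, min_size=5)
        assert s.sizes.min() >= 5
        assert len(s) == 500

    def test_integer_output(self, zipf_cdf):
        s = br.sample_sizes_from_cdf(zipf_cdf, 100, rng_seed=3, min_size=2)
        assert np.array_equal(s.sizes, np.floor(s.sizes))

    def test_mean_matches_numeric_integral(self):
        """Monte-Carlo mean vs a dense-grid evaluation of the same
        truncated, rounded inverse map (independent numeric oracle)."""
        n_F = 3585
        fitted = 10 ** 2.3 / np.arange(1, n_F + 1) ** 0.39
        cdf = br.fitted_rank_to_cdf(fitted, n_F)
        grid = np.linspace(0.5 / 2_000_000, 1 - 0.5 / 2_000_000, 2_000_000)
        g = np.floor(np.interp(grid, np.arange(1, n_F + 1) / n_F, fitted) + 0.5)
        g = g[g >= 2]
        oracle_mean, oracle_sd = g.mean(), g.std()
        s = br.sample_sizes_from_cdf(cdf, 10_000, rng_seed=7, min_size=2)
        se = oracle_sd / np.sqrt(10_000)
        assert abs(s.sizes.mean() - oracle_mean) < 3 * se

    def test_degenerate_cdf_rejected(self):
        cdf = br.fitted_rank_to_cdf(np.array([0.4, 0.3, 0.2, 0.1]), 4)
        with pytest.raises(DegenerateCdfError):
            br.sample_sizes_from_cdf(cdf, 50, rng_seed=0, min_size=2)


class TestPvalueArithmetic:
    @pytest.mark.parametrize(
        "larger,equal,reps,expected",
        [
            (9692, 46, 10000, 0.97),  # rounds to 0.97 at two decimals
            (2, 0, 10000, 0.0002),
            (1618, 2180, 10000, 0.38),
            (10, 0, 10, 1.0),
            (0, 0, 10, 0.0),
        ],
    )
    def test_tie_inclusive_rule(self, larger, equal, reps, expected):
        assert br.pvalue_from_counts(larger, equal, reps) == pytest.approx(expected, abs=5e-3)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            br.pvalue_from_counts(8, 5, 10)


class TestEmpiricalPvalue:
    @pytest.fixture
    def null_ranked(self):
        """Data drawn from the very Zipf CDF the test refits."""
        fitted = 10 ** 2.3 / np.arange(1, 301) ** 0.5
        cdf = br.fitted_rank_to_cdf(fitted, 300)
        sample = br.sample_sizes_from_cdf(cdf, 300, rng_seed=123, min_size=2)
        return br.rank_sizes(sample, min_size=2)

    def test_reproducible_under_seed(self, null_ranked):
        r1 = br.empirical_pvalue(null_ranked, "zipf", n_reps=50, rng_seed=9)
        r2 = br.empirical_pvalue(null_ranked, "zipf", n_reps=50, rng_seed=9)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.replicate_ks, r2.replicate_ks)

    def test_counts_consistent(self, null_ranked):
        res = br.empirical_pvalue(null_ranked, "zipf", n_reps=60, rng_seed=4)
        assert res.n_larger + res.n_equal <= res.n_reps
        assert res.p_value == pytest.approx((res.n_larger + res.n_equal) / res.n_reps)
        assert np.all(res.replicate_ks >= 0) and np.all(res.replicate_ks <= 1)

    def test_null_data_large_p(self, null_ranked):
        res = br.empirical_pvalue(null_ranked, "zipf", n_reps=100, rng_seed=0)
        assert res.p_value > 0.05

    def test_misspecified_model_small_p(self):
        """Strongly bent beta data should reject a Zipf fit."""
        n = 300
        r = np.arange(1, n + 1, dtype=float)
        fitted = 10.0 * (n + 1 - r) ** 0.8 / r ** 0.16
        cdf = br.fitted_rank_to_cdf(fitted, n)
        sample = br.sample_sizes_from_cdf(cdf, n, rng_seed=5, min_size=2)
        ranked = br.rank_sizes(sample, min_size=2)
        res = br.empirical_pvalue(ranked, "zipf", n_reps=100, rng_seed=1)
        assert res.p_value < 0.05

    def test_results_method_matches_function(self, null_ranked):
        via_results = br.ZipfRankModel(null_ranked).fit().resample_pvalue(n_reps=30, seed=2)
        direct = br.empirical_pvalue(null_ranked, "zipf", n_reps=30, rng_seed=2)
        assert via_results.p_value == direct.p_value
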