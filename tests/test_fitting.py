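"""Rank-function fitting, goodness of fit, AIC/BIC and model comparison."""

import warnings

import numpy as np
import pytest

import betarank as br
from betarank.fit import InsufficientDataError, N_PARAMS


def brute_force_ols(X, y):
    """Normal-equations OLS, the independent oracle for small problems."""
    XtX = [[sum(X[i][a] * X[i][b] for i in range(len(X))) for b in range(len(X[0]))] for a in range(len(X[0]))]
    Xty = [sum(X[i][a] * y[i] for i in range(len(X))) for a in range(len(X[0]))]
    return np.linalg.solve(np.array(XtX), np.array(Xty))


class TestLogLogFits:
    def test_zipf_noiseless_recovery(self, zipf_ranked):
        fit = br.fit_zipf_loglog(zipf_ranked)
        assert fit.params.a == pytest.approx(0.5, abs=1e-9)
        assert fit.params.log_c == pytest.approx(2.0, abs=1e-9)
        assert fit.mse < 1e-18

    def test_beta_noiseless_recovery(self):
        n = 80
        r = np.arange(1, n + 1, dtype=float)
        sizes = 10.0 ** 1.8 * (n + 1 - r) ** 0.34 / r ** 0.85
        fit = br.fit_beta_loglog(br.RankedSizes(sizes))
        assert fit.params.a == pytest.approx(0.85, abs=1e-9)
        assert fit.params.b == pytest.approx(0.34, abs=1e-9)
        assert fit.params.log_C == pytest.approx(1.8, abs=1e-9)

    def test_beta_on_zipf_data_gives_zero_b(self, zipf_ranked):
        fit = br.fit_beta_loglog(zipf_ranked)
        assert abs(fit.params.b) < 1e-9
        assert fit.params.a == pytest.approx(0.5, abs=1e-9)

    def test_three_point_zipf_slope(self):
        fit = br.fit_zipf_loglog(br.RankedSizes([4, 2, 1]))
        # oracle: normal equations on the same 3-point log-log problem
        X = [[1.0, np.log10(r)] for r in (1, 2, 3)]
        y = [np.log10(s) for s in (4, 2, 1)]
        coef = brute_force_ols(X, y)
        assert fit.params.a == pytest.approx(-coef[1], abs=1e-12)
        assert fit.params.a == pytest.approx(1.23, abs=0.005)

    def test_nesting_beta_never_worse(self, noisy_zipf_ranked):
        zf = br.fit_zipf_loglog(noisy_zipf_ranked)
        bf = br.fit_beta_loglog(noisy_zipf_ranked)
        assert bf.gof.sse <= zf.gof.sse + 1e-12

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            br.fit_zipf_loglog(br.RankedSizes([3, 2]))
        with pytest.raises(InsufficientDataError):
            br.fit_beta_loglog(br.RankedSizes([4, 3, 2]))

    def test_ols_matches_brute_force_on_small_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(4, 11)
            sizes = np.sort(rng.uniform(2, 400, size=n))[::-1]
            ranked = br.RankedSizes(sizes)
            for fitter, cols in ((br.fit_zipf_loglog, 1), (br.fit_beta_loglog, 2)):
                fit = fitter(ranked)
                r = np.arange(1, n + 1, dtype=float)
                if cols == 1:
                    X = [[1.0, np.log10(ri)] for ri in r]
                else:
                    X = [[1.0, np.log10(n + 1 - ri), np.log10(ri)] for ri in r]
                coef = brute_force_ols(X, np.log10(sizes))
                assert fit.fittedvalues_log == pytest.approx(np.array(X) @ coef, abs=1e-12)


class TestNonlinearFit:
    def test_matches_loglog_on_noiseless_data(self, zipf_ranked):
        nl = br.fit_rank_nonlinear(zipf_ranked, "zipf")
        ll = br.fit_zipf_loglog(zipf_ranked)
        assert nl.params.a == pytest.approx(ll.params.a, abs=1e-6)
        assert nl.params.log_c == pytest.approx(ll.params.log_c, abs=1e-6)
        assert nl.converged

    def test_linear_mse_dominance_under_noise(self, noisy_zipf_ranked):
        """Nonlinear minimises linear-scale SSE, so it cannot lose to the
        loglog fit in that scale."""
        nl = br.fit_rank_nonlinear(noisy_zipf_ranked, "zipf")
        ll = br.fit_zipf_loglog(noisy_zipf_ranked)
        sse_nl = np.sum((noisy_zipf_ranked.sizes - nl.fittedvalues) ** 2)
        sse_ll = np.sum((noisy_zipf_ranked.sizes - ll.fittedvalues) ** 2)
        assert sse_nl <= sse_ll + 1e-9

    def test_constant_data_degenerate(self):
        ranked = br.RankedSizes([7, 7, 7, 7, 7])
        fit = br.fit_rank_nonlinear(ranked, "zipf")
        assert fit.params.a == pytest.approx(0.0, abs=1e-6)
        assert 10 ** fit.params.log_c == pytest.approx(7.0, rel=1e-6)

    def test_beta_nonlinear_recovery(self):
        n = 60
        r = np.arange(1, n + 1, dtype=float)
        sizes = 100.0 * (n + 1 - r) ** 0.3 / r ** 0.7
        fit = br.fit_rank_nonlinear(br.RankedSizes(sizes), "beta")
        assert fit.params.a == pytest.approx(0.7, abs=1e-5)
        assert fit.params.b == pytest.approx(0.3, abs=1e-5)


class TestHistogramPowerlaw:
    def test_noiseless_slope_recovery(self):
        S = 2.0 ** np.arange(1, 7)  # 2..64
        counts = np.round(1e9 * S ** -3.1).astype(int)  # large c: rounding negligible
        hist = br.SizeHistogram(S, counts, scale="linear")
        fit = br.fit_histogram_powerlaw(hist, min_count=1)
        assert fit.slope == pytest.approx(-3.1, abs=5e-3)

    def test_three_bin_toy(self):
        hist = br.SizeHistogram([2, 4, 8], [8, 2, 1], scale="linear")
        fit = br.fit_histogram_powerlaw(hist)
        assert fit.slope == pytest.approx(-1.5, abs=1e-9)

    def test_min_count_filters_singleton_bins(self):
        hist = br.SizeHistogram([2, 3, 4, 5, 20], [8, 4, 2, 2, 1], scale="linear")
        fit = br.fit_histogram_powerlaw(hist, min_count=2)
        assert fit.n_bins_used == 4

    def test_too_few_bins(self):
        hist = br.SizeHistogram([2, 4], [3, 1], scale="linear")
        with pytest.raises(InsufficientDataError):
            br.fit_histogram_powerlaw(hist)


class TestGofMetrics:
    def test_identity(self):
        g = br.gof_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], scale="linear")
        assert g.mse == 0 and g.pearson_oe == pytest.approx(1.0) and g.r_squared == pytest.approx(1.0)

    def test_hand_mse(self):
        g = br.gof_metrics([1.0, 2.0], [2.0, 4.0], scale="linear")
        assert g.mse == pytest.approx(2.5)
        assert g.sse == pytest.approx(5.0)

    def test_r_squared_is_squared_pearson(self, noisy_zipf_ranked):
        fit = br.fit_zipf_loglog(noisy_zipf_ranked)
        g = fit.gof
        assert g.r_squared == pytest.approx(g.pearson_oe ** 2, abs=1e-15)

    def test_constant_expected_reported_undefined(self):
        with pytest.warns(RuntimeWarning):
            g = br.gof_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], scale="linear")
        assert np.isnan(g.pearson_oe) and np.isnan(g.r_squared)
        assert g.mse == pytest.approx((1 + 0 + 1) / 3)


class TestKsDistance:
    @pytest.mark.parametrize(
        "obs,fit,expected",
        [
            ([3, 5, 8], [3, 5, 8], 0.0),
            ([1, 1], [2, 2], 1.0),
            ([1, 2], [1, 3], 0.5),
        ],
    )
    def test_hand_values(self, obs, fit, expected):
        assert br.ks_distance(obs, fit) == pytest.approx(expected)

    def test_bounds(self, noisy_zipf_ranked):
        fit = br.fit_zipf_loglog(noisy_zipf_ranked)
        assert 0 <= fit.ks <= 1


class TestModelScore:
    def test_monotone_in_mse(self):
        a1 = br.model_score(0.01, 100, 2).aic
        a2 = br.model_score(0.02, 100, 2).aic
        assert a1 < a2

    def test_parameter_penalty_is_two(self):
        s2 = br.model_score(0.05, 300, 2)
        s3 = br.model_score(0.05, 300, 3)
        assert s3.aic - s2.aic == pytest.approx(2.0)
        assert s3.bic - s2.bic == pytest.approx(np.log(300))

    def test_gaussian_likelihood_oracle(self):
        """AIC equals -2*logL + 2p minus the declared constant n(1+ln 2pi)."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 2000))
            mse = float(rng.uniform(1e-4, 5.0))
            p = int(rng.integers(1, 5))
            s = br.model_score(mse, n, p)
            loglik = -n / 2 * np.log(2 * np.pi * mse) - n * mse / (2 * mse)
            assert s.log_lik == pytest.approx(loglik, rel=1e-12)
            const = n * (1 + np.log(2 * np.pi))
            assert s.aic == pytest.approx(-2 * loglik + 2 * p - const, abs=1e-8)

    def test_perfect_fit_warns(self):
        with pytest.warns(RuntimeWarning):
            s = br.model_score(0.0, 10, 2)
        assert s.aic == -np.inf


class TestModelComparison:
    def test_equal_mse_penalises_beta(self):
        ft = br.comparison_first_term(717, 0.05, 0.05)
        assert ft == 0.0

    def test_printed_first_term(self):
        ft = br.comparison_first_term(717, 0.0179, 0.079)
        assert ft == pytest.approx(-1065.9, rel=2e-3)

    def test_log_base_invariance(self):
        """Rescaling both MSEs by the same factor (a change of log base in
        the residual scale) leaves the first term unchanged."""
        k = (np.log(10) / np.log(2)) ** 2
        assert br.comparison_first_term(500, 0.02 * k, 0.08 * k) == pytest.approx(
            br.comparison_first_term(500, 0.02, 0.08), rel=1e-12
        )

    def test_compare_on_beta_data_prefers_beta(self):
        n = 200
        r = np.arange(1, n + 1, dtype=float)
        sizes = 5.0 * (n + 1 - r) ** 0.8 / r ** 0.2
        rng = np.random.default_rng(2)
        sizes = sizes * 10 ** rng.normal(0, 0.03, n)
        cmp_ = br.compare_beta_vs_zipf(br.RankedSizes(np.sort(sizes)[::-1]))
        assert cmp_.delta_aic == pytest.approx(cmp_.first_term + 2)
        assert cmp_.delta_bic == pytest.approx(cmp_.first_term + np.log(n))
        assert cmp_.beta_preferred_aic and cmp_.beta_preferred_bic


class TestModelClasses:
    def test_from_sizes_and_summary(self):
        model = br.ZipfRankModel.from_sizes([50, 20, 10, 5, 3, 2], min_size=2)
        res = model.fit()
        assert res.n_F == 6 and res.p == N_PARAMS["zipf"]
        text = res.summary()
        assert "Zipf" in text and "AIC" in text

    def test_results_predict_matches_fittedvalues(self, zipf_ranked):
        res = br.BetaRankModel(zipf_ranked).fit()
        pred = res.predict(zipf_ranked.ranks)
        assert np.allclose(pred, res.fittedvalues, rtol=1e-10)

    def test_to_dict_json_safe(self, noisy_zipf_ranked):
        import json

        d = br.ZipfRankModel(noisy_zipf_ranked).fit().to_dict()
        json.dumps(d)
        assert d["model"] == "zipf" and d["gof"]["scale"] == "log"
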