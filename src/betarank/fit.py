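"""Fitting rank functions and histogram power laws; goodness of fit; AIC/BIC.

Two regression routes per rank function, as used throughout the rank-size
literature:

* ``loglog`` — ordinary least squares on log10(S_r) against log10(r)
  (and log10(n_F+1-r) for the beta function); residuals are minimised in
  the log scale.  This is the default, and reported MSE/R2 are computed in
  the scale in which the regression was carried out.
* ``nonlinear`` — least squares in the linear S_r scale, started from the
  loglog solution.

Model comparison assumes Gaussian residuals, so sigma^2 is estimated by the
MSE and, up to an additive constant that is fixed across models fitted to
the same data,

    AIC = n_F * ln(MSE) + 2p        BIC = n_F * ln(MSE) + p * ln(n_F)

with p = 2 for Zipf (c, a) and p = 3 for beta (C, a, b).  The dropped
constant is n_F * (1 + ln(2*pi)); ``ModelScore.log_lik`` keeps it, so
-2*log_lik + 2p reproduces the full-likelihood AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import BetaRankParams, ZipfParams, beta_rank_value, zipf_rank_value
from .ranked import RankedSizes, SizeHistogram, SizeSample, empirical_cdf_of_sizes, rank_sizes

__all__ = [
    "GofMetrics",
    "ModelScore",
    "ModelComparison",
    "RankFitResults",
    "HistogramFit",
    "RankSizeModel",
    "ZipfRankModel",
    "BetaRankModel",
    "fit_zipf_loglog",
    "fit_beta_loglog",
    "fit_rank_nonlinear",
    "fit_histogram_powerlaw",
    "gof_metrics",
    "ks_distance",
    "model_score",
    "compare_beta_vs_zipf",
]

N_PARAMS = {"zipf": 2, "beta": 3}


class InsufficientDataError(ValueError):
    pass


class FitConvergenceError(RuntimeError):
    def __init__(self, message: str, best: "RankFitResults | None" = None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class GofMetrics:
    """Goodness-of-fit measures for one fitted rank function.

    ``pearson_oe`` is the Pearson correlation between observed and expected
    values (in the declared scale); ``r_squared`` is its square.  ``ks`` is
    the Kolmogorov-Smirnov distance between the observed-size CDF and the
    fitted-size CDF, always computed on the linear size scale.  When the
    expected values are constant the correlation is undefined and both
    correlation fields are NaN.
    """

    mse: float
    sse: float
    pearson_oe: float
    r_squared: float
    ks: float
    scale: str = "log"

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "sse": self.sse,
            "pearson_oe": self.pearson_oe,
            "r_squared": self.r_squared,
            "ks": self.ks,
            "scale": self.scale,
        }


@dataclass(frozen=True)
class ModelScore:
    """Gaussian-residual likelihood score of a fit.

    ``log_lik`` is the full maximised Gaussian log-likelihood with
    sigma^2 = MSE; ``aic``/``bic`` drop the shared constant
    n_F*(1 + ln(2*pi)) so that only differences across models are
    meaningful (they are what is compared).
    """

    sigma2_hat: float
    log_lik: float
    p: int
    n_F: int
    aic: float
    bic: float

    def to_dict(self) -> dict:
        return {
            "sigma2_hat": self.sigma2_hat,
            "log_lik": self.log_lik,
            "p": self.p,
            "n_F": self.n_F,
            "aic": self.aic,
            "bic": self.bic,
        }


def model_score(mse: float, n_F: int, p: int) -> ModelScore:
    """AIC/BIC from the regression MSE under Gaussian residuals."""
    if mse < 0:
        raise ValueError("mse must be >= 0")
    if n_F < 1 or p < 1:
        raise ValueError("n_F and p must be >= 1")
    if mse == 0:
        warnings.warn("perfect fit (MSE=0): AIC/BIC reported as -inf", RuntimeWarning)
        return ModelScore(0.0, np.inf, p, n_F, -np.inf, -np.inf)
    log_lik = -0.5 * n_F * (np.log(2.0 * np.pi * mse) + 1.0)
    aic = n_F * np.log(mse) + 2.0 * p
    bic = n_F * np.log(mse) + p * np.log(n_F)
    return ModelScore(float(mse), float(log_lik), int(p), int(n_F), float(aic), float(bic))


def ks_distance(observed_sizes, fitted_sizes) -> float:
    """Max vertical distance between the empirical CDFs of two size sets.

    Evaluated over the union of both supports (both CDFs are step
    functions, so the supremum is attained at a support point).
    """
    obs = observed_sizes.sizes if isinstance(observed_sizes, (SizeSample, RankedSizes)) else np.asarray(observed_sizes, dtype=float)
    fit = fitted_sizes.sizes if isinstance(fitted_sizes, (SizeSample, RankedSizes)) else np.asarray(fitted_sizes, dtype=float)
    if obs.size == 0 or fit.size == 0:
        raise ValueError("both size sets must be non-empty")
    grid = np.union1d(obs, fit)
    cdf_o = np.searchsorted(np.sort(obs), grid, side="right") / obs.size
    cdf_f = np.searchsorted(np.sort(fit), grid, side="right") / fit.size
    return float(np.max(np.abs(cdf_o - cdf_f)))


def gof_metrics(observed, expected, scale: str = "log", sizes_observed=None, sizes_fitted=None) -> GofMetrics:
    """MSE, SSE, Pearson r and R^2 between observed and expected values.

    ``observed``/``expected`` are in the declared scale (log10 values for
    ``scale='log'``).  The KS distance is computed on the linear size scale
    from ``sizes_observed``/``sizes_fitted`` when given, else by
    exponentiating log-scale inputs.
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if O.shape != E.shape or O.size < 2:
        raise ValueError("observed and expected must align, length >= 2")
    resid = O - E
    sse = float(np.sum(resid ** 2))
    mse = sse / O.size
    if np.ptp(E) == 0 or np.ptp(O) == 0:
        warnings.warn("constant observed/expected values: correlation undefined", RuntimeWarning)
        r = np.nan
    else:
        r = float(np.corrcoef(O, E)[0, 1])
    if sizes_observed is None:
        sizes_observed = 10.0 ** O if scale == "log" else O
    if sizes_fitted is None:
        sizes_fitted = 10.0 ** E if scale == "log" else E
    ks = ks_distance(np.asarray(sizes_observed, dtype=float), np.asarray(sizes_fitted, dtype=float))
    return GofMetrics(mse=mse, sse=sse, pearson_oe=r, r_squared=r ** 2 if np.isfinite(r) else np.nan, ks=ks, scale=scale)


# ---------------------------------------------------------------------------
# OLS core


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and their standard errors."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


# ---------------------------------------------------------------------------
# results object


@dataclass(frozen=True)
class RankFitResults:
    """Results of fitting a rank function to ranked family sizes.

    Attributes
    ----------
    model : "zipf" | "beta"
    method : "loglog_linear" | "nonlinear"
    params : ZipfParams | BetaRankParams
    bse : standard errors of the regression coefficients, ordered like the
        parameter fields (log intercept first); NaN for the nonlinear route.
    fittedvalues : expected sizes E_r on the linear scale, aligned with ranks.
    scale : scale in which residuals were minimised ("log" or "linear").
    """

    model: str
    method: str
    params: ZipfParams | BetaRankParams
    ranked: RankedSizes
    fittedvalues: np.ndarray
    bse: np.ndarray
    scale: str
    converged: bool = True

    # -- derived quantities ------------------------------------------------

    @property
    def n_F(self) -> int:
        return self.ranked.n_F

    @property
    def fittedvalues_log(self) -> np.ndarray:
        return np.log10(self.fittedvalues)

    @property
    def gof(self) -> GofMetrics:
        if self.scale == "log":
            return gof_metrics(
                np.log10(self.ranked.sizes),
                self.fittedvalues_log,
                scale="log",
                sizes_observed=self.ranked.sizes,
                sizes_fitted=self.fittedvalues,
            )
        return gof_metrics(
            self.ranked.sizes,
            self.fittedvalues,
            scale="linear",
            sizes_observed=self.ranked.sizes,
            sizes_fitted=self.fittedvalues,
        )

    @property
    def mse(self) -> float:
        return self.gof.mse

    @property
    def r_squared(self) -> float:
        return self.gof.r_squared

    @property
    def ks(self) -> float:
        return self.gof.ks

    @property
    def p(self) -> int:
        return N_PARAMS[self.model]

    @property
    def score(self) -> ModelScore:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return model_score(self.mse, self.n_F, self.p)

    @property
    def aic(self) -> float:
        return self.score.aic

    @property
    def bic(self) -> float:
        return self.score.bic

    def predict(self, r) -> np.ndarray | float:
        """Expected size at rank(s) r under the fitted function."""
        if self.model == "zipf":
            return zipf_rank_value(self.params, r)
        return beta_rank_value(self.params, r)

    def resample_pvalue(self, n_reps: int = 10000, seed: int = 0):
        """Empirical p-value of this fit via inverse-CDF resampling."""
        from .resample import empirical_pvalue

        return empirical_pvalue(self.ranked, self.model, n_reps=n_reps, rng_seed=seed, method=self.method)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "method": self.method,
            "params": self.params.to_dict(),
            "bse": [float(x) for x in np.atleast_1d(self.bse)],
            "n_F": self.n_F,
            "scale": self.scale,
            "converged": self.converged,
            "gof": self.gof.to_dict(),
            "score": self.score.to_dict(),
        }

    def summary(self) -> str:
        g, s = self.gof, self.score
        lines = [
            f"{'Beta' if self.model == 'beta' else 'Zipf'} rank function fit ({self.method})",
            "=" * 48,
            f"n_F (families):     {self.n_F}",
            f"min size:           {self.ranked.min_size:g}",
        ]
        if self.model == "zipf":
            pz = self.params
            lines += [
                f"log10(c):           {pz.log_c:.4f} (se {self.bse[0]:.4f})",
                f"a:                  {pz.a:.4f} (se {self.bse[1]:.4f})",
            ]
        else:
            pb = self.params
            lines += [
                f"log10(C):           {pb.log_C:.4f} (se {self.bse[0]:.4f})",
                f"a:                  {pb.a:.4f} (se {self.bse[1]:.4f})",
                f"b:                  {pb.b:.4f} (se {self.bse[2]:.4f})",
            ]
        lines += [
            f"MSE ({g.scale} scale):   {g.mse:.4g}",
            f"R^2:                {g.r_squared:.4f}",
            f"KS distance:        {g.ks:.4f}",
            f"AIC / BIC:          {s.aic:.1f} / {s.bic:.1f}   (p={s.p})",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fitting routines


def fit_rank_curve_loglog(sizes, model: str = "zipf") -> tuple:
    """OLS rank-function fit for observations whose rank is known a priori.

    ``sizes[i]`` is taken to sit at rank i+1 without re-sorting.  Re-ranking
    noisy observations before fitting biases the slope upward (sorting
    stretches the extremes), so calibration studies that know the true rank
    of each observation should fit in generation order.  Returns
    ``(params, bse)``.
    """
    y = np.log10(np.asarray(sizes, dtype=float))
    n = y.size
    if n < N_PARAMS[model] + 1:
        raise InsufficientDataError("too few observations")
    r = np.arange(1, n + 1, dtype=float)
    if model == "zipf":
        X = np.column_stack([np.ones(n), np.log10(r)])
        beta, bse = _ols(X, y)
        return ZipfParams(log_c=float(beta[0]), a=float(-beta[1])), bse
    X = np.column_stack([np.ones(n), np.log10(n + 1.0 - r), np.log10(r)])
    beta, bse = _ols(X, y)
    return BetaRankParams(log_C=float(beta[0]), a=float(-beta[2]), b=float(beta[1]), n_F=n), bse


def fit_zipf_loglog(ranked: RankedSizes) -> RankFitResults:
    """OLS of log10(S_r) on log10(r): recovers (log c, a) with a > 0 for
    decreasing data."""
    if ranked.n_F < 3:
        raise InsufficientDataError("Zipf loglog fit needs n_F >= 3")
    r = ranked.ranks.astype(float)
    y = np.log10(ranked.sizes)
    X = np.column_stack([np.ones_like(r), np.log10(r)])
    beta, bse = _ols(X, y)
    params = ZipfParams(log_c=float(beta[0]), a=float(-beta[1]))
    fitted_log = X @ beta
    return RankFitResults(
        model="zipf",
        method="loglog_linear",
        params=params,
        ranked=ranked,
        fittedvalues=10.0 ** fitted_log,
        bse=bse,
        scale="log",
    )


def fit_beta_loglog(ranked: RankedSizes) -> RankFitResults:
    """Two-regressor OLS: log10(S_r) on log10(n_F+1-r) and log10(r)."""
    n = ranked.n_F
    if n < 4:
        raise InsufficientDataError("beta loglog fit needs n_F >= 4")
    r = ranked.ranks.astype(float)
    y = np.log10(ranked.sizes)
    X = np.column_stack([np.ones_like(r), np.log10(n + 1.0 - r), np.log10(r)])
    beta, bse = _ols(X, y)
    params = BetaRankParams(log_C=float(beta[0]), a=float(-beta[2]), b=float(beta[1]), n_F=n)
    fitted_log = X @ beta
    return RankFitResults(
        model="beta",
        method="loglog_linear",
        params=params,
        ranked=ranked,
        fittedvalues=10.0 ** fitted_log,
        bse=bse,
        scale="log",
    )


def fit_rank_nonlinear(ranked: RankedSizes, model: str = "zipf") -> RankFitResults:
    """Least squares in the linear S_r scale, started from the loglog fit."""
    if model not in N_PARAMS:
        raise ValueError("model must be 'zipf' or 'beta'")
    start = fit_zipf_loglog(ranked) if model == "zipf" else fit_beta_loglog(ranked)
    r = ranked.ranks.astype(float)
    S = ranked.sizes
    n = ranked.n_F

    if model == "zipf":
        x0 = [start.params.log_c, start.params.a]

        def resid(theta):
            return 10.0 ** theta[0] / r ** theta[1] - S

    else:
        x0 = [start.params.log_C, start.params.a, start.params.b]

        def resid(theta):
            return 10.0 ** theta[0] * (n + 1.0 - r) ** theta[2] / r ** theta[1] - S

    sol = least_squares(resid, x0=x0, method="lm" if len(S) > len(x0) else "trf")
    theta = sol.x
    if model == "zipf":
        params = ZipfParams(log_c=float(theta[0]), a=float(theta[1]))
        fitted = 10.0 ** theta[0] / r ** theta[1]
    else:
        params = BetaRankParams(log_C=float(theta[0]), a=float(theta[1]), b=float(theta[2]), n_F=n)
        fitted = 10.0 ** theta[0] * (n + 1.0 - r) ** theta[2] / r ** theta[1]
    results = RankFitResults(
        model=model,
        method="nonlinear",
        params=params,
        ranked=ranked,
        fittedvalues=fitted,
        bse=np.full(len(x0), np.nan),
        scale="linear",
        converged=bool(sol.success),
    )
    if not sol.success:
        raise FitConvergenceError(f"nonlinear {model} fit did not converge: {sol.message}", best=results)
    return results


@dataclass(frozen=True)
class HistogramFit:
    """Power-law fit of a size histogram: log10(count) regressed on
    log10(size) (linear histograms) or on the log-size bin midpoint."""

    slope: float
    intercept: float
    gof: GofMetrics
    n_bins_used: int


def fit_histogram_powerlaw(hist: SizeHistogram, min_count: int = 1) -> HistogramFit:
    """Fit log10(count) ~ log10(size); bins with count < min_count (and
    empty bins) are excluded first."""
    keep = hist.counts >= max(min_count, 1)
    if keep.sum() < 3:
        raise InsufficientDataError("need >= 3 bins above min_count to fit")
    x = hist.bin_values[keep] if hist.scale == "log" else np.log10(hist.bin_values[keep])
    y = np.log10(hist.counts[keep].astype(float))
    X = np.column_stack([np.ones_like(x), x])
    beta, _ = _ols(X, y)
    fitted = X @ beta
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        g = gof_metrics(y, fitted, scale="log", sizes_observed=10.0 ** y, sizes_fitted=10.0 ** fitted)
    return HistogramFit(slope=float(beta[1]), intercept=float(beta[0]), gof=g, n_bins_used=int(keep.sum()))


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ModelComparison:
    """AIC/BIC difference beta - Zipf on the same ranked data.

    ``first_term`` = n_F * ln(MSE_beta / MSE_zipf) is shared by both
    criteria and is invariant to the log base of the residual scale;
    delta_aic = first_term + 2 and delta_bic = first_term + ln(n_F)
    (the penalty difference for one extra parameter).  Negative values
    favour the beta rank function.
    """

    n_F: int
    mse_beta: float
    mse_zipf: float
    first_term: float
    delta_aic: float
    delta_bic: float
    beta_fit: RankFitResults | None = None
    zipf_fit: RankFitResults | None = None

    @property
    def beta_preferred_aic(self) -> bool:
        return self.delta_aic < 0

    @property
    def beta_preferred_bic(self) -> bool:
        return self.delta_bic < 0

    def to_dict(self) -> dict:
        return {
            "n_F": self.n_F,
            "mse_beta": self.mse_beta,
            "mse_zipf": self.mse_zipf,
            "first_term": self.first_term,
            "delta_aic": self.delta_aic,
            "delta_bic": self.delta_bic,
            "beta_preferred_aic": self.beta_preferred_aic,
            "beta_preferred_bic": self.beta_preferred_bic,
        }


def comparison_first_term(n_F: int, mse_beta: float, mse_zipf: float) -> float:
    """n_F * ln(MSE_beta / MSE_zipf), the term shared by delta-AIC and delta-BIC."""
    if mse_beta <= 0 or mse_zipf <= 0:
        raise ValueError("MSEs must be positive")
    return float(n_F * np.log(mse_beta / mse_zipf))


def compare_beta_vs_zipf(ranked: RankedSizes, method: str = "loglog") -> ModelComparison:
    """Fit both rank functions and report the AIC/BIC differences."""
    if method == "loglog":
        zf = fit_zipf_loglog(ranked)
        bf = fit_beta_loglog(ranked)
    else:
        zf = fit_rank_nonlinear(ranked, "zipf")
        bf = fit_rank_nonlinear(ranked, "beta")
    ft = comparison_first_term(ranked.n_F, bf.mse, zf.mse)
    return ModelComparison(
        n_F=ranked.n_F,
        mse_beta=bf.mse,
        mse_zipf=zf.mse,
        first_term=ft,
        delta_aic=ft + 2.0,
        delta_bic=ft + float(np.log(ranked.n_F)),
        beta_fit=bf,
        zipf_fit=zf,
    )


# ---------------------------------------------------------------------------
# model classes


class RankSizeModel:
    """Base class binding ranked data to a rank-function family.

    Use :class:`ZipfRankModel` or :class:`BetaRankModel`; ``fit`` returns a
    :class:`RankFitResults`.
    """

    model_name: str = ""

    def __init__(self, ranked: RankedSizes):
        self.ranked = ranked

    @classmethod
    def from_sizes(cls, sizes, min_size: float = 1, exclude_top: int = 0, labels=None):
        sample = SizeSample(np.asarray(sizes, dtype=float), tuple(labels) if labels else None)
        return cls(rank_sizes(sample, min_size=min_size, exclude_top=exclude_top))

    @classmethod
    def from_sample(cls, sample: SizeSample, min_size: float = 1, exclude_top: int = 0):
        return cls(rank_sizes(sample, min_size=min_size, exclude_top=exclude_top))

    def fit(self, method: str = "loglog") -> RankFitResults:
        if method in ("loglog", "loglog_linear"):
            return self._fit_loglog()
        if method == "nonlinear":
            return fit_rank_nonlinear(self.ranked, self.model_name)
        raise ValueError("method must be 'loglog' or 'nonlinear'")

    def _fit_loglog(self) -> RankFitResults:  # pragma: no cover - abstract
        raise NotImplementedError


class ZipfRankModel(RankSizeModel):
    """Zipf (inverse power-law) rank function S_r = c / r^a."""

    model_name = "zipf"

    def _fit_loglog(self) -> RankFitResults:
        return fit_zipf_loglog(self.ranked)


class BetaRankModel(RankSizeModel):
    """Beta rank function S_r = C (n_F+1-r)^b / r^a."""

    model_name = "beta"

    def _fit_loglog(self) -> RankFitResults:
        return fit_beta_loglog(self.ranked)
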