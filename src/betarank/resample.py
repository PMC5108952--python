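"""Empirical p-values for a fitted rank function via inverse-CDF resampling.

The idea (bootstrap goodness-of-fit in the style used for power-law
testing): a rank plot converts directly to a cumulative plot, so a fitted
rank function defines a CDF.  Replicate samples drawn from that CDF, each
re-ranked and re-fitted with the same function family, give a null
distribution of KS distances; the proportion of replicate distances at
least as large as the observed one is the empirical p-value.  A small
p-value rejects the fitted function for the data.

Steps per replicate: draw uniforms y in (0,1); map through the inverse of
the fitted CDF (piecewise-linear in rank orientation: probability r/n_F at
the fitted size of rank r); round to integers; discard values below the
observed minimum size and redraw; rank; refit; record the KS distance of
the replicate to its own fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fit import (
    InsufficientDataError,
    RankFitResults,
    fit_beta_loglog,
    fit_rank_nonlinear,
    fit_zipf_loglog,
    ks_distance,
)
from .ranked import RankedSizes, SizeSample, rank_sizes

__all__ = [
    "FittedCdf",
    "PvalueResult",
    "fitted_rank_to_cdf",
    "sample_sizes_from_cdf",
    "empirical_pvalue",
    "pvalue_from_counts",
]

KS_TIE_TOL = 1e-12


class DegenerateCdfError(RuntimeError):
    pass


@dataclass(frozen=True)
class FittedCdf:
    """CDF induced by a fitted rank function.

    ``support`` holds the fitted sizes in increasing order with lower-tail
    probabilities ``cum_prob`` (j/n_F at the j-th smallest fitted size).
    The inverse map works in rank orientation: probability r/n_F returns
    the fitted size at rank r, interpolating linearly between rank grid
    points and clamping to the endpoint sizes outside the grid.
    """

    support: np.ndarray
    cum_prob: np.ndarray
    _upper_p: np.ndarray  # r/n_F, increasing
    _sizes_desc: np.ndarray  # fitted sizes, descending

    def inverse(self, y) -> np.ndarray | float:
        y_arr = np.asarray(y, dtype=float)
        out = np.interp(y_arr, self._upper_p, self._sizes_desc)
        return float(out) if out.ndim == 0 else out

    def cum_prob_at(self, x) -> np.ndarray | float:
        """Rank-orientation probability at size x (inverse of ``inverse``)."""
        x_arr = np.asarray(x, dtype=float)
        # sizes ascending vs upper-tail probability descending
        out = np.interp(x_arr, self._sizes_desc[::-1], self._upper_p[::-1])
        return float(out) if out.ndim == 0 else out


def fitted_rank_to_cdf(fit: RankFitResults | np.ndarray, n_F: int | None = None) -> FittedCdf:
    """Build the CDF of a fitted rank function.

    Accepts either fit results or a bare sequence of fitted sizes in rank
    order (descending).  The fitted values must be positive and strictly
    decreasing for the curve to define a valid CDF.
    """
    if isinstance(fit, RankFitResults):
        fitted = np.asarray(fit.fittedvalues, dtype=float)
        n = fit.n_F
    else:
        fitted = np.asarray(fit, dtype=float)
        n = n_F if n_F is not None else fitted.size
    if fitted.size != n:
        raise ValueError("fitted values must align with n_F")
    if np.any(fitted <= 0):
        raise ValueError("fitted sizes must be positive")
    if np.any(np.diff(fitted) >= 0):
        raise ValueError("fitted values must be strictly decreasing to define a cdf")
    upper_p = np.arange(1, n + 1) / n
    support = fitted[::-1].copy()
    cum_prob = np.arange(1, n + 1) / n
    return FittedCdf(support=support, cum_prob=cum_prob, _upper_p=upper_p, _sizes_desc=fitted.copy())


def sample_sizes_from_cdf(
    cdf: FittedCdf,
    n: int,
    rng_seed: int | np.random.Generator = 0,
    min_size: float = 2,
) -> SizeSample:
    """Draw n integer sizes from a fitted CDF by inverse-transform sampling.

    Uniform draws are mapped through the inverse CDF and rounded half-up to
    integers; values below ``min_size`` are discarded and redrawn until n
    values are retained.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    out: list[np.ndarray] = []
    got = 0
    drawn = 0
    while got < n:
        batch = max(2 * (n - got), 16)
        y = rng.uniform(0.0, 1.0, size=batch)
        x = np.floor(cdf.inverse(y) + 0.5)  # round half-up
        x = x[x >= min_size]
        drawn += batch
        got += x.size
        out.append(x)
        if drawn >= 100 * n and got < max(1, drawn // 100):
            raise DegenerateCdfError("acceptance rate below 1%: cdf incompatible with min_size")
    sizes = np.concatenate(out)[:n]
    return SizeSample(sizes)


@dataclass(frozen=True)
class PvalueResult:
    """Empirical p-value of a rank-function fit.

    p = (n_larger + n_equal) / n_reps — replicate KS distances at least as
    large as the observed one count toward the p-value (ties included, the
    conservative rule; both counts are reported so the strict variant can
    be recovered).
    """

    observed_ks: float
    replicate_ks: np.ndarray
    n_reps: int
    n_larger: int
    n_equal: int
    n_failed: int
    p_value: float
    seed: int
    model: str

    def to_dict(self, include_replicates: bool = False) -> dict:
        d = {
            "observed_ks": self.observed_ks,
            "n_reps": self.n_reps,
            "n_larger": self.n_larger,
            "n_equal": self.n_equal,
            "n_failed": self.n_failed,
            "p_value": self.p_value,
            "seed": self.seed,
            "model": self.model,
        }
        if include_replicates:
            d["replicate_ks"] = [float(x) for x in self.replicate_ks]
        return d


def pvalue_from_counts(n_larger: int, n_equal: int, n_reps: int) -> float:
    """p = (n_larger + n_equal)/n_reps; ties count toward the p-value."""
    if n_reps < 1 or n_larger < 0 or n_equal < 0 or n_larger + n_equal > n_reps:
        raise ValueError("invalid replicate counts")
    return (n_larger + n_equal) / n_reps


def _fit(ranked: RankedSizes, model: str, method: str) -> RankFitResults:
    if method == "nonlinear":
        return fit_rank_nonlinear(ranked, model)
    return fit_zipf_loglog(ranked) if model == "zipf" else fit_beta_loglog(ranked)


def empirical_pvalue(
    ranked: RankedSizes,
    model: str = "zipf",
    n_reps: int = 10000,
    rng_seed: int = 0,
    method: str = "loglog",
    max_failure_frac: float = 0.05,
) -> PvalueResult:
    """Resampling p-value for fitting ``ranked`` with the given rank function.

    Each replicate draws n_F sizes from the CDF of the observed data's fit,
    ranks them, refits the same model family, and records the KS distance
    between the replicate and its own fit.  Replicates whose refit fails
    are dropped (counted in ``n_failed``); more than ``max_failure_frac``
    failures aborts.  Per-replicate RNG substreams are derived from
    (rng_seed, replicate index), so results are reproducible and
    independent of execution order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    obs_fit = _fit(ranked, model, method)
    observed_ks = ks_distance(ranked.sizes, obs_fit.fittedvalues)
    cdf = fitted_rank_to_cdf(obs_fit)
    threshold = float(ranked.sizes.min())  # discard simulated sizes below the observed minimum
    n = ranked.n_F

    replicate_ks = np.empty(n_reps)
    n_ok = 0
    n_failed = 0
    for i in range(n_reps):
        rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, i])
        sample = sample_sizes_from_cdf(cdf, n, rng, min_size=threshold)
        try:
            rep_ranked = rank_sizes(sample, min_size=threshold)
            rep_fit = _fit(rep_ranked, model, method)
        except (InsufficientDataError, ValueError):
            n_failed += 1
            continue
        replicate_ks[n_ok] = ks_distance(rep_ranked.sizes, rep_fit.fittedvalues)
        n_ok += 1
    if n_failed > max_failure_frac * n_reps:
        raise RuntimeError(f"{n_failed}/{n_reps} replicate fits failed")
    replicate_ks = replicate_ks[:n_ok]
    if n_failed:
        warnings.warn(f"{n_failed} replicate fits failed and were dropped", RuntimeWarning)
    n_larger = int(np.sum(replicate_ks > observed_ks + KS_TIE_TOL))
    n_equal = int(np.sum(np.abs(replicate_ks - observed_ks) <= KS_TIE_TOL))
    p = pvalue_from_counts(n_larger, n_equal, n_ok)
    return PvalueResult(
        observed_ks=float(observed_ks),
        replicate_ks=replicate_ks,
        n_reps=n_ok,
        n_larger=n_larger,
        n_equal=n_equal,
        n_failed=n_failed,
        p_value=p,
        seed=int(rng_seed),
        model=model,
    )
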