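"""Seeded generators of family-size samples.

Two kinds of generator:

* rank-model samples — deterministic Zipf or beta rank-function values at
  ranks 1..n, optionally perturbed by multiplicative noise on the log10
  scale (``noise_sd`` is the standard deviation of that log10 noise, so a
  log-log regression residual sd estimates it directly);
* i.i.d. alternative distributions — uniform, absolute normal, lognormal
  and chi-square draws, used as initial conditions for the split-merge
  simulator.

All generators round half-up to integers (real family sizes are counts)
and floor at ``min_size``; rounding can be disabled for exact-recovery
checks.  The default Zipf regime (a=0.39, n=3586, sizes >= 2) mimics the
human Ensembl paralogue collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import BetaRankParams, ZipfParams, beta_rank_value, zipf_rank_value
from .ranked import SizeSample

__all__ = [
    "SyntheticSpec",
    "generate_rank_model_sizes",
    "generate_alt_sizes",
    "generate",
    "paralogue_like_spec",
]

RANK_FAMILIES = ("zipf", "beta")
ALT_FAMILIES = ("uniform", "abs_normal", "lognormal", "chisq")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic size sample."""

    family: str
    params: dict
    n: int
    noise_sd: float = 0.0
    seed: int = 0
    min_size: int = 1
    integerize: bool = True

    def __post_init__(self) -> None:
        if self.family not in RANK_FAMILIES + ALT_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


def paralogue_like_spec(seed: int = 0, n: int = 3586, a: float = 0.39, noise_sd: float = 0.05) -> SyntheticSpec:
    """Default fixture mimicking the human paralogue regime.

    A Zipf rank function with exponent ~0.39 whose largest family has a few
    hundred genes and whose smallest retained families have two.
    """
    log_c = np.log10(2.0) + a * np.log10(n)  # size ~2 at the last rank
    return SyntheticSpec(
        family="zipf",
        params={"log_c": float(log_c), "a": a},
        n=n,
        noise_sd=noise_sd,
        seed=seed,
        min_size=2,
    )


def _finalize(values: np.ndarray, spec: SyntheticSpec) -> SizeSample:
    if not np.all(np.isfinite(values)):
        raise ValueError("generator produced non-finite sizes; check parameters")
    if spec.integerize:
        values = np.floor(values + 0.5)  # round half-up
    values = np.maximum(values, spec.min_size)
    return SizeSample(values)


def generate_rank_model_sizes(spec: SyntheticSpec) -> SizeSample:
    """Sizes from a rank function at ranks 1..n with optional log10 noise."""
    if spec.family not in RANK_FAMILIES:
        raise ValueError("family must be 'zipf' or 'beta'")
    r = np.arange(1, spec.n + 1, dtype=float)
    if spec.family == "zipf":
        params = ZipfParams(log_c=float(spec.params["log_c"]), a=float(spec.params["a"]))
        values = zipf_rank_value(params, r)
    else:
        params = BetaRankParams(
            log_C=float(spec.params["log_C"]),
            a=float(spec.params["a"]),
            b=float(spec.params["b"]),
            n_F=spec.n,
        )
        values = beta_rank_value(params, r)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values * 10.0 ** rng.normal(0.0, spec.noise_sd, size=spec.n)
    return _finalize(np.asarray(values, dtype=float), spec)


def generate_alt_sizes(spec: SyntheticSpec) -> SizeSample:
    """I.i.d. sizes from one of the alternative initial distributions.

    Parameter keys: uniform(low, high); abs_normal(mean, sd);
    lognormal(mu, sigma) on the natural-log scale; chisq(df, scale).
    """
    if spec.family not in ALT_FAMILIES:
        raise ValueError(f"family must be one of {ALT_FAMILIES}")
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.family == "uniform":
        low, high = float(p["low"]), float(p["high"])
        if high < low:
            raise ValueError("uniform requires high >= low")
        values = rng.uniform(low, high, size=spec.n)
    elif spec.family == "abs_normal":
        sd = float(p["sd"])
        if sd < 0:
            raise ValueError("abs_normal requires sd >= 0")
        values = np.abs(rng.normal(float(p["mean"]), sd, size=spec.n))
    elif spec.family == "lognormal":
        sigma = float(p["sigma"])
        if sigma < 0:
            raise ValueError("lognormal requires sigma >= 0")
        values = rng.lognormal(float(p["mu"]), sigma, size=spec.n)
    else:  # chisq
        df = float(p["df"])
        if df <= 0:
            raise ValueError("chisq requires df > 0")
        values = rng.chisquare(df, size=spec.n) * float(p.get("scale", 1.0))
    return _finalize(values, spec)


def generate(spec: SyntheticSpec) -> SizeSample:
    """Dispatch to the right generator for the spec's family."""
    if spec.family in RANK_FAMILIES:
        return generate_rank_model_sizes(spec)
    return generate_alt_sizes(spec)
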