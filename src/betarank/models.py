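"""The two rank functions and the rank/density exponent conversion.

Zipf (inverse power-law) rank function:

    S_r = c / r^a            i.e.  log(S_r) = log(c) - a*log(r)

Beta rank function, a two-exponent generalisation that also bends at the
small-size end of the ranking:

    S_r = C * (n_F + 1 - r)^b / r^a

which reduces to the Zipf form at b = 0.  Intercepts are stored as log10
values (the scale in which the regressions are run); the exponents a and b
are invariant to the log base.

A Zipf rank exponent ``a`` corresponds to a power-law probability density
f(S) ∝ 1/S^alpha with alpha = 1/a + 1 (axis swap plus differentiation).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ZipfParams",
    "BetaRankParams",
    "DensityExponent",
    "zipf_rank_value",
    "beta_rank_value",
    "rank_to_density_exponent",
    "density_to_rank_exponent",
]


@dataclass(frozen=True)
class ZipfParams:
    """Zipf rank-function parameters: S_r = 10**log_c / r**a."""

    log_c: float
    a: float

    def to_dict(self) -> dict:
        return {"model": "zipf", **asdict(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ZipfParams":
        return cls(log_c=float(d["log_c"]), a=float(d["a"]))

    @property
    def c(self) -> float:
        return float(10.0 ** self.log_c)


@dataclass(frozen=True)
class BetaRankParams:
    """Beta rank-function parameters: S_r = 10**log_C * (n_F+1-r)**b / r**a."""

    log_C: float
    a: float
    b: float
    n_F: int

    def __post_init__(self) -> None:
        if self.n_F < 1:
            raise ValueError("n_F must be >= 1")

    def to_dict(self) -> dict:
        return {"model": "beta", **asdict(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "BetaRankParams":
        return cls(
            log_C=float(d["log_C"]), a=float(d["a"]), b=float(d["b"]), n_F=int(d["n_F"])
        )


@dataclass(frozen=True)
class DensityExponent:
    """Exponent alpha of the size density f(S) ∝ S^(-alpha) implied by a rank fit."""

    alpha: float


def zipf_rank_value(params: ZipfParams, r) -> np.ndarray | float:
    """Evaluate S_r = c / r^a; r may be a scalar or array, each >= 1."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 1):
        raise ValueError("rank must be >= 1")
    out = 10.0 ** params.log_c / r_arr ** params.a
    return float(out) if out.ndim == 0 else out


def beta_rank_value(params: BetaRankParams, r) -> np.ndarray | float:
    """Evaluate S_r = C (n_F+1-r)^b / r^a for ranks 1 <= r <= n_F.

    Continuous (non-integer) ranks inside the range are accepted; they are
    used when inverting the fitted curve into a CDF.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 1) or np.any(r_arr > params.n_F):
        raise ValueError(f"rank must lie in [1, n_F={params.n_F}]")
    out = 10.0 ** params.log_C * (params.n_F + 1.0 - r_arr) ** params.b / r_arr ** params.a
    return float(out) if out.ndim == 0 else out


def rank_to_density_exponent(a: float) -> DensityExponent:
    """Convert a Zipf rank exponent to the density exponent alpha = 1/a + 1."""
    if a <= 0:
        raise ValueError("rank exponent a must be > 0")
    return DensityExponent(alpha=1.0 / a + 1.0)


def density_to_rank_exponent(alpha: float) -> float:
    """Inverse conversion: a = 1/(alpha - 1)."""
    if alpha <= 1:
        raise ValueError("density exponent alpha must be > 1")
    return 1.0 / (alpha - 1.0)
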