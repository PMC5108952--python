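"""Containers and summaries for family-size samples.

A *family* here is any grouping of genes — a paralogue family produced by
ancestral duplication, or a curated gene set grouped by function.  The only
datum the rank-size machinery needs is the family's size ``S`` (its member
count), so the containers hold bare size vectors, optionally labelled.

Sizes are positive reals rather than strictly integers: real family sizes
are integers, but exact rank-function values (used for noiseless model
recovery and for fitted CDFs) are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SizeSample",
    "RankedSizes",
    "SizeHistogram",
    "EmpiricalCdf",
    "rank_sizes",
    "size_histogram",
    "log_size_histogram",
    "empirical_cdf_of_sizes",
    "read_size_file",
    "write_size_file",
]


class EmptyFilterError(ValueError):
    """No families pass the size filter."""


def _as_size_array(sizes: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(sizes) if not isinstance(sizes, np.ndarray) else sizes, dtype=float)
    if arr.ndim != 1:
        raise ValueError("sizes must be one-dimensional")
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 1)):
        raise ValueError("every family size must be finite and >= 1")
    return arr


@dataclass(frozen=True)
class SizeSample:
    """A bag of family sizes, optionally labelled by family.

    Parameters
    ----------
    sizes
        Family sizes, each >= 1.
    labels
        Optional family labels aligned with ``sizes``; must be unique.
    """

    sizes: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = _as_size_array(self.sizes)
        object.__setattr__(self, "sizes", arr)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != arr.size:
                raise ValueError("labels must align with sizes")
            if len(set(labels)) != len(labels):
                raise ValueError("labels must be unique")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.sizes.size)

    @property
    def total_genes(self) -> float:
        return float(self.sizes.sum())


@dataclass(frozen=True)
class RankedSizes:
    """Family sizes sorted descending; rank r = 1..n_F.

    ``min_size`` records the inclusion threshold that was applied; every
    retained size is >= min_size.
    """

    sizes: np.ndarray
    min_size: float = 1
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = _as_size_array(self.sizes)
        if arr.size == 0:
            raise EmptyFilterError("no families pass filter")
        if np.any(np.diff(arr) > 0):
            raise ValueError("ranked sizes must be non-increasing")
        if np.any(arr < self.min_size):
            raise ValueError("all ranked sizes must be >= min_size")
        object.__setattr__(self, "sizes", arr)

    @property
    def n_F(self) -> int:
        return int(self.sizes.size)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, self.n_F + 1)

    def __len__(self) -> int:
        return self.n_F

    def as_sample(self) -> SizeSample:
        return SizeSample(self.sizes.copy(), self.labels)


@dataclass(frozen=True)
class SizeHistogram:
    """Counts of families per size value (linear) or per log-size bin."""

    bin_values: np.ndarray
    counts: np.ndarray
    scale: str = "linear"  # "linear" | "log"

    def __post_init__(self) -> None:
        bv = np.asarray(self.bin_values, dtype=float)
        ct = np.asarray(self.counts, dtype=int)
        if bv.size != ct.size:
            raise ValueError("bin_values and counts must align")
        if np.any(np.diff(bv) <= 0):
            raise ValueError("bin_values must be strictly increasing")
        if np.any(ct < 0):
            raise ValueError("counts must be non-negative")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        object.__setattr__(self, "bin_values", bv)
        object.__setattr__(self, "counts", ct)

    @property
    def n_families(self) -> int:
        return int(self.counts.sum())


def rank_sizes(
    sample: SizeSample | Sequence[float],
    min_size: float = 1,
    exclude_top: int = 0,
) -> RankedSizes:
    """Rank family sizes from largest to smallest.

    Families smaller than ``min_size`` are dropped first; the ``exclude_top``
    largest of the survivors are then removed (the largest human paralogue
    family, a 225-gene zinc-finger family, dominates fits and is commonly
    excluded).  Ties are broken by family label (lexicographic) when labels
    are present, otherwise by insertion order — either way the ranking is
    reproducible.

    Raises
    ------
    EmptyFilterError
        If no family survives the filters.
    """
    if not isinstance(sample, SizeSample):
        sample = SizeSample(np.asarray(sample, dtype=float))
    if exclude_top < 0:
        raise ValueError("exclude_top must be >= 0")
    sizes = sample.sizes
    keep = sizes >= min_size
    sizes = sizes[keep]
    labels = None
    if sample.labels is not None:
        labels = [l for l, k in zip(sample.labels, keep) if k]
    if sizes.size == 0:
        raise EmptyFilterError("no families pass filter")
    if labels is not None:
        order = sorted(range(sizes.size), key=lambda i: (-sizes[i], labels[i]))
    else:
        order = np.argsort(-sizes, kind="stable")
    sizes = sizes[np.asarray(order)]
    if labels is not None:
        labels = tuple(labels[i] for i in order)
    if exclude_top:
        if exclude_top >= sizes.size:
            raise EmptyFilterError("no families pass filter")
        sizes = sizes[exclude_top:]
        if labels is not None:
            labels = labels[exclude_top:]
    return RankedSizes(sizes, min_size=min_size, labels=labels)


def size_histogram(sample: SizeSample | Sequence[float]) -> SizeHistogram:
    """One bin per distinct size; exact counts f(S)."""
    if not isinstance(sample, SizeSample):
        sample = SizeSample(np.asarray(sample, dtype=float))
    if len(sample) == 0:
        raise ValueError("sample must be non-empty")
    values, counts = np.unique(sample.sizes, return_counts=True)
    return SizeHistogram(values, counts, scale="linear")


def log_size_histogram(sample: SizeSample | Sequence[float], n_bins: int) -> SizeHistogram:
    """Histogram of log10(size) with ``n_bins`` equal-width bins.

    Coarse-grains the large-family tail; bin midpoints are reported on the
    log10 scale.  Counts are conserved (they sum to the sample length).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not isinstance(sample, SizeSample):
        sample = SizeSample(np.asarray(sample, dtype=float))
    if len(sample) == 0:
        raise ValueError("sample must be non-empty")
    logs = np.log10(sample.sizes)
    lo, hi = logs.min(), logs.max()
    if hi == lo:
        # degenerate: all sizes equal — widen the range so everything lands in one bin
        hi = lo + 1.0
    counts, edges = np.histogram(logs, bins=n_bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    return SizeHistogram(mids, counts, scale="log")


@dataclass(frozen=True)
class EmpiricalCdf:
    """Right-continuous empirical CDF of a size sample."""

    support: np.ndarray  # increasing distinct sizes
    cum_prob: np.ndarray  # P(X <= support[i])

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.support, x, side="right")
        probs = np.concatenate([[0.0], self.cum_prob])
        out = probs[idx]
        return float(out) if out.ndim == 0 else out


def empirical_cdf_of_sizes(sample: SizeSample | Sequence[float]) -> EmpiricalCdf:
    """Empirical cumulative distribution of family sizes.

    At the smallest rank r of any tied size in the descending ranking,
    cdf(S_r) = 1 - (r-1)/n_F, so the rank plot converts directly to the
    cumulative plot.
    """
    if not isinstance(sample, SizeSample):
        sample = SizeSample(np.asarray(sample, dtype=float))
    if len(sample) == 0:
        raise ValueError("sample must be non-empty")
    values, counts = np.unique(sample.sizes, return_counts=True)
    cum = np.cumsum(counts) / counts.sum()
    return EmpiricalCdf(values, cum)


def read_size_file(path) -> SizeSample:
    """Read one size per line (blank lines ignored)."""
    sizes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                sizes.append(float(line))
    return SizeSample(np.asarray(sizes, dtype=float))


def write_size_file(sample: SizeSample, path) -> None:
    with open(path, "w") as fh:
        for s in sample.sizes:
            fh.write(f"{int(s) if float(s).is_integer() else s}\n")
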