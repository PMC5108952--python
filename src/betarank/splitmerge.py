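"""Split-merge dynamics of curated gene-set sizes.

A curator of a gene-set collection occasionally (i) splits the largest
set(s) in two, having recognised sub-functional categories, and (ii) merges
a small fraction of randomly chosen sets pairwise when a common theme is
realised.  Iterating these two operations on an initially power-law
collection of sizes bends the rank plot away from a straight line toward a
beta-rank shape with b > a.  Both operations conserve the total gene count;
only the number of sets and their sizes change.

Defaults: one split of the largest set and merging of 6% of all sets per
round, 100 rounds, snapshots every 10 rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ranked import SizeSample

__all__ = ["SplitMergeConfig", "SimTrajectory", "split_largest", "merge_random", "run_split_merge"]


@dataclass(frozen=True)
class SplitMergeConfig:
    """Parameters of the split-merge process.

    merge_fraction : fraction of current sets merged each round (two-to-one,
        so the set count drops by half the merged count).
    split_top_k : how many of the largest sets are split each round.
    min_part : smallest allowed part of a split (1 permits singleton sets).
    split_first : split before merging within a round (default), so a
        freshly merged set cannot be split in the same round.
    """

    merge_fraction: float = 0.06
    split_top_k: int = 1
    rounds: int = 100
    snapshot_every: int = 10
    seed: int = 0
    min_part: int = 1
    split_first: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.merge_fraction < 1:
            raise ValueError("merge_fraction must be in [0, 1)")
        if self.split_top_k < 0 or self.rounds < 0 or self.min_part < 1:
            raise ValueError("invalid configuration")


@dataclass
class SimTrajectory:
    """Trajectory of a split-merge run.

    snapshots : list of (round index, SizeSample), always including round 0
        and the final round reached.
    family_counts : set count after each round (index 0 = initial state).
    merge_counts : number of sets merged (m_t) in each round, so the exact
        bookkeeping n_{t+1} = n_t + k_t - m_t/2 can be audited.
    split_counts : number of splits actually performed each round.
    """

    snapshots: list[tuple[int, SizeSample]]
    total_genes: int
    family_counts: list[int]
    merge_counts: list[int]
    split_counts: list[int]
    config: SplitMergeConfig
    status: str = "completed"

    @property
    def final_sizes(self) -> SizeSample:
        return self.snapshots[-1][1]

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "total_genes": self.total_genes,
            "rounds_completed": len(self.family_counts) - 1,
            "family_counts": self.family_counts,
            "merge_counts": self.merge_counts,
            "split_counts": self.split_counts,
            "snapshot_rounds": [r for r, _ in self.snapshots],
            "seed": self.config.seed,
            "merge_fraction": self.config.merge_fraction,
            "split_top_k": self.config.split_top_k,
        }


def split_largest(
    sizes: SizeSample | np.ndarray,
    k: int = 1,
    rng: np.random.Generator | int = 0,
    min_part: int = 1,
) -> SizeSample:
    """Split each of the k largest sets into two parts.

    The split point is uniform on {min_part, ..., S - min_part}; a targeted
    set smaller than 2*min_part cannot be split and is skipped with a
    warning.  Total gene count is conserved.
    """
    arr = sizes.sizes.copy() if isinstance(sizes, SizeSample) else np.asarray(sizes, dtype=float).copy()
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if k == 0 or arr.size == 0:
        return SizeSample(arr)
    k = min(k, arr.size)
    order = np.argsort(-arr, kind="stable")[:k]
    keep_mask = np.ones(arr.size, dtype=bool)
    new_parts: list[float] = []
    for idx in order:
        s = int(arr[idx])
        if s < 2 * min_part:
            warnings.warn(f"set of size {s} too small to split with min_part={min_part}; skipped", RuntimeWarning)
            continue
        cut = int(rng.integers(min_part, s - min_part + 1))
        keep_mask[idx] = False
        new_parts.extend([float(cut), float(s - cut)])
    return SizeSample(np.concatenate([arr[keep_mask], np.asarray(new_parts)]) if new_parts else arr)


def merge_random(
    sizes: SizeSample | np.ndarray,
    fraction: float,
    rng: np.random.Generator | int = 0,
) -> SizeSample:
    """Merge a fraction of randomly chosen sets pairwise (two-to-one).

    m = floor(fraction * n) rounded down to even sets are chosen uniformly
    without replacement and paired at random; each pair is replaced by one
    set of the summed size.  Any set may be chosen — no size threshold, so
    no discontinuity is introduced into the distribution.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    arr = sizes.sizes.copy() if isinstance(sizes, SizeSample) else np.asarray(sizes, dtype=float).copy()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = arr.size
    m = int(np.floor(fraction * n))
    m -= m % 2
    if m == 0:
        return SizeSample(arr)
    chosen = rng.choice(n, size=m, replace=False)
    pairs = chosen.reshape(-1, 2)
    merged = arr[pairs[:, 0]] + arr[pairs[:, 1]]
    keep_mask = np.ones(n, dtype=bool)
    keep_mask[chosen] = False
    return SizeSample(np.concatenate([arr[keep_mask], merged]))


def run_split_merge(initial: SizeSample | np.ndarray, config: SplitMergeConfig) -> SimTrajectory:
    """Iterate the split-merge dynamics and record snapshots.

    Snapshots are taken at round 0, every ``snapshot_every`` rounds, and at
    the final round.  If the set count would drop below 4 the run halts
    with a partial trajectory and status "halted".  Deterministic under a
    fixed seed.
    """
    sample = initial if isinstance(initial, SizeSample) else SizeSample(np.asarray(initial, dtype=float))
    if len(sample) == 0:
        raise ValueError("initial sample must be non-empty")
    rng = np.random.default_rng(config.seed)
    current = SizeSample(sample.sizes.copy())
    total = current.total_genes
    snapshots = [(0, current)]
    family_counts = [len(current)]
    merge_counts: list[int] = []
    split_counts: list[int] = []
    status = "completed"

    for t in range(1, config.rounds + 1):
        n_before = len(current)
        ops = ["split", "merge"] if config.split_first else ["merge", "split"]
        m_t = 0
        k_t = 0
        for op in ops:
            if op == "split":
                before = len(current)
                current = split_largest(current, config.split_top_k, rng, config.min_part)
                k_t = len(current) - before
            else:
                before = len(current)
                current = merge_random(current, config.merge_fraction, rng)
                m_t = 2 * (before - len(current))
        merge_counts.append(m_t)
        split_counts.append(k_t)
        family_counts.append(len(current))
        assert current.total_genes == total, "gene count must be conserved"
        is_snapshot = (config.snapshot_every and t % config.snapshot_every == 0) or t == config.rounds
        if len(current) < 4:
            status = "halted"
            snapshots.append((t, current))
            break
        if is_snapshot:
            snapshots.append((t, current))
    if status == "completed" and snapshots[-1][0] != config.rounds:
        snapshots.append((config.rounds, current))
    return SimTrajectory(
        snapshots=snapshots,
        total_genes=int(total),
        family_counts=family_counts,
        merge_counts=merge_counts,
        split_counts=split_counts,
        config=config,
        status=status,
    )
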