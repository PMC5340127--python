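"""Matched random interval sets: the Monte-Carlo null for overlap counts.

Each random set reproduces the observed summit-window set's interval count
and length multiset, but places every interval uniformly over the genome:
a chromosome is drawn with probability proportional to its length (restricted
to chromosomes long enough to hold the interval) and the start uniformly
within the admissible range.  Random intervals may overlap each other and no
gap or blacklist masking is applied — the null is the plain uniform-placement
model.

Reproducibility is counter-based: the RNG stream for random set ``k`` is
seeded from ``(seed, k)``, so any set can be regenerated in isolation and
sets are independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from repeatpeaks.genomic_io import Genome, Interval, RepeatFeature
from repeatpeaks.interval_engine import RepeatIndex, SummitWindow, windows_to_arrays

__all__ = ["RandomSetConfig", "NullCounts", "sample_random_set", "generate_null_counts"]


@dataclass(frozen=True)
class RandomSetConfig:
    """Parameters of the matched-random-set null.

    ``lengths`` is the interval-length multiset to match; when None it is
    taken from the observed windows at null-generation time.  The default of
    500 sets matches the published procedure.
    """

    genome: Genome
    n_sets: int = 500
    seed: int = 0
    lengths: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if self.lengths is not None:
            _check_lengths(self.lengths, self.genome)

    @classmethod
    def from_windows(
        cls, windows: Sequence[SummitWindow], genome: Genome,
        n_sets: int = 500, seed: int = 0,
    ) -> "RandomSetConfig":
        lengths = tuple(len(w.interval) for w in windows)
        return cls(genome=genome, n_sets=n_sets, seed=seed, lengths=lengths)


@dataclass(frozen=True)
class NullCounts:
    """Per-key null overlap-count vectors, one entry per random set."""

    counts: dict[str, np.ndarray]
    n_sets: int
    by: str
    mode: str

    def __getitem__(self, key: str) -> np.ndarray:
        if key in self.counts:
            return self.counts[key]
        return np.zeros(self.n_sets, dtype=np.int64)


def _check_lengths(lengths: Sequence[int], genome: Genome) -> None:
    if len(lengths) == 0:
        raise ValueError("lengths multiset is empty")
    max_chrom = max(length for _, length in genome.items())
    too_long = [L for L in lengths if L > max_chrom]
    if too_long:
        raise ValueError(
            f"interval length {max(too_long)} exceeds every chromosome "
            f"(longest is {max_chrom} bp)"
        )
    if min(lengths) < 1:
        raise ValueError("interval lengths must be >= 1")


def _sample_window_arrays(
    genome: Genome, lengths: Sequence[int], seed: int, set_index: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Draw one matched random set as per-chromosome coordinate arrays.

    Unique lengths are processed in ascending order with a fixed draw
    sequence, so the result depends only on (genome, length multiset, seed,
    set_index).
    """
    rng = np.random.default_rng([seed, set_index])
    chrom_names = genome.names
    chrom_lengths = np.asarray([genome[c] for c in chrom_names], dtype=np.int64)
    lengths_arr = np.asarray(lengths, dtype=np.int64)

    chosen_chrom = np.empty(len(lengths_arr), dtype=np.int64)
    starts = np.empty(len(lengths_arr), dtype=np.int64)
    for L in np.unique(lengths_arr):
        idx = np.flatnonzero(lengths_arr == L)
        admissible = np.flatnonzero(chrom_lengths >= L)
        if admissible.size == 0:
            raise ValueError(f"no chromosome can hold an interval of length {L}")
        weights = chrom_lengths[admissible].astype(float)
        weights /= weights.sum()
        picks = admissible[rng.choice(admissible.size, size=idx.size, p=weights)]
        chosen_chrom[idx] = picks
        # start uniform on [0, chromLen - L] inclusive
        starts[idx] = rng.integers(0, chrom_lengths[picks] - L + 1)

    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci in np.unique(chosen_chrom):
        idx = np.flatnonzero(chosen_chrom == ci)
        s = starts[idx]
        arrays[chrom_names[ci]] = (s, s + lengths_arr[idx])
    return arrays


def sample_random_set(config: RandomSetConfig, set_index: int) -> list[Interval]:
    """Generate random set ``set_index`` as a list of intervals.

    Fully reproducible from (config.seed, set_index); intervals are returned
    in the order of the configured length multiset grouped by chromosome.
    """
    if config.lengths is None:
        raise ValueError("config.lengths must be set to sample a standalone random set")
    _check_lengths(config.lengths, config.genome)
    arrays = _sample_window_arrays(config.genome, config.lengths, config.seed, set_index)
    intervals = []
    for chrom in sorted(arrays):
        s, e = arrays[chrom]
        intervals.extend(
            Interval(chrom, int(a), int(b)) for a, b in zip(s.tolist(), e.tolist())
        )
    return intervals


def generate_null_counts(
    windows: Sequence[SummitWindow],
    repeats: Sequence[RepeatFeature],
    config: RandomSetConfig,
    by: str = "family",
    mode: str = "pairs",
) -> NullCounts:
    """Count overlaps for every random set of the null.

    The random sets match the observed windows' count and length multiset
    only — observed positions are never consulted.  Counting uses the same
    grouping and mode as the observed count, over the keys present in the
    repeat annotation (keys never hit get all-zero vectors).
    """
    if len(windows) == 0:
        raise ValueError("windows must be nonempty")
    lengths = config.lengths
    if lengths is None:
        lengths = tuple(len(w.interval) for w in windows)
    _check_lengths(lengths, config.genome)

    index = RepeatIndex(repeats, by=by)
    matrix = {key: np.zeros(config.n_sets, dtype=np.int64) for key in index.keys}
    for k in range(config.n_sets):
        arrays = _sample_window_arrays(config.genome, lengths, config.seed, k)
        for key, count in index.count(arrays, mode=mode).items():
            matrix[key][k] = count
    return NullCounts(matrix, config.n_sets, by, mode)
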