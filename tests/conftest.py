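"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (double loops,
rank-based formulas) kept free of any package internals, so they can
arbitrate the vectorised implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from repeatpeaks.genomic_io import Genome, Interval, Peak, RepeatFeature
from repeatpeaks.interval_engine import SummitWindow


def brute_force_overlap_counts(windows, repeats, by="family", mode="pairs"):
    """O(n*m) double-loop grouped overlap counter (the oracle)."""
    counts = {}
    for rep in repeats:
        key = rep.rep_family if by == "family" else rep.rep_name
        if not key:
            continue
        counts.setdefault(key, 0)
    for w in windows:
        wi = w.interval if isinstance(w, SummitWindow) else w
        seen = set()
        for rep in repeats:
            key = rep.rep_family if by == "family" else rep.rep_name
            if not key:
                continue
            ri = rep.interval
            if wi.chrom == ri.chrom and wi.start < ri.end and ri.start < wi.end:
                if mode == "pairs":
                    counts[key] += 1
                else:
                    seen.add(key)
        for key in seen:
            counts[key] += 1
    return counts


def bh_oracle(p_values):
    """Rank-based Benjamini-Hochberg step-up, straight from the definition."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def random_interval_fixture(rng, n_windows, n_repeats, n_chroms=3, chrom_len=10_000,
                            families=("Alu", "MIR", "L2")):
    """A random (windows, repeats) pair on a small shared genome."""
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    windows = []
    for _ in range(n_windows):
        chrom = chroms[rng.integers(n_chroms)]
        start = int(rng.integers(0, chrom_len - 200))
        windows.append(Interval(chrom, start, start + int(rng.integers(1, 200))))
    repeats = []
    for j in range(n_repeats):
        chrom = chroms[rng.integers(n_chroms)]
        start = int(rng.integers(0, chrom_len - 500))
        family = families[rng.integers(len(families))]
        repeats.append(
            RepeatFeature(
                Interval(chrom, start, start + int(rng.integers(1, 500))),
                rep_name=f"{family}_{j % 5}",
                rep_class="SINE",
                rep_family=family,
            )
        )
    return windows, repeats


@pytest.fixture
def small_genome():
    return Genome([("chr1", 10_000), ("chr2", 5_000)])


@pytest.fixture
def simple_peak():
    def make(chrom="chr1", start=900, end=1100, summit=1000, ef=10.0, fdr=0.0, label="p"):
        return Peak(Interval(chrom, start, end), summit, ef, fdr, label)

    return make
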