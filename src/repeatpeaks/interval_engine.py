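"""Deterministic interval computations.

Summit windows, grouped window-vs-repeat overlap counting, peak selection by
caller scores, nearest-TSS proximity classification, and summit-sequence
extraction.

Overlap counting is the pipeline's hot inner loop (it runs once per random
set in the Monte-Carlo null), so repeats are pre-indexed into per-(chromosome,
key) sorted coordinate arrays and each query is two binary searches per
window batch.  Two overlapping intervals share at least one base; touching
half-open intervals do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from repeatpeaks.genomic_io import Genome, Interval, Peak, RepeatFeature

__all__ = [
    "SummitWindow",
    "OverlapCounts",
    "RepeatIndex",
    "make_summit_windows",
    "windows_to_arrays",
    "count_overlaps",
    "select_peaks",
    "classify_tss_proximity",
    "extract_summit_sequences",
]

#: chromosome -> (window starts, window ends), both int64 arrays
WindowArrays = Mapping[str, tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class SummitWindow:
    """A fixed-width window centred on a peak summit, clamped to the chromosome."""

    interval: Interval
    source_peak: Peak


@dataclass(frozen=True)
class OverlapCounts:
    """Grouped overlap counts at one granularity.

    ``by`` is the grouping key (repeat family or element name); ``mode`` is
    the counting rule — ``pairs`` counts every overlapping (window, repeat)
    pair, ``distinct_windows`` counts windows with at least one overlap of
    that key.
    """

    counts: dict[str, int]
    by: str
    mode: str

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)


def make_summit_windows(
    peaks: Sequence[Peak], genome: Genome, width: int = 100
) -> list[SummitWindow]:
    """Build width-bp windows centred on peak summits.

    The window is [summit - floor(width/2), summit - floor(width/2) + width),
    clamped to [0, chromosome length); clamping shrinks the window rather
    than shifting it.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    windows = []
    for peak in peaks:
        chrom = peak.chrom
        if chrom not in genome:
            raise ValueError(f"peak chromosome {chrom!r} absent from genome")
        half = width // 2
        start = peak.summit - half
        end = start + width
        start = max(start, 0)
        end = min(end, genome[chrom])
        windows.append(SummitWindow(Interval(chrom, start, end), peak))
    return windows


def windows_to_arrays(windows: Sequence[SummitWindow]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group windows by chromosome into (starts, ends) arrays for counting."""
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for w in windows:
        starts, ends = by_chrom.setdefault(w.interval.chrom, ([], []))
        starts.append(w.interval.start)
        ends.append(w.interval.end)
    return {
        chrom: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
        for chrom, (s, e) in by_chrom.items()
    }


class RepeatIndex:
    """Sorted-array index of repeat features, grouped by (chromosome, key).

    For a window [ws, we) and a key's repeats on the same chromosome, the
    number of overlapping repeats is::

        #(rep.start < we) - #(rep.end <= ws)

    where both terms are binary searches into the key's independently sorted
    start and end arrays.  In family granularity, features with an empty
    family are excluded (name-encoded BED rows without taxonomy take part
    only in element-level statistics).
    """

    def __init__(self, repeats: Iterable[RepeatFeature], by: str = "family"):
        if by not in ("family", "element"):
            raise ValueError(f"unknown grouping {by!r} (use 'family' or 'element')")
        self.by = by
        grouped: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        keys: dict[str, None] = {}
        for rep in repeats:
            key = rep.rep_family if by == "family" else rep.rep_name
            if not key:
                continue
            keys.setdefault(key, None)
            starts, ends = grouped.setdefault((rep.interval.chrom, key), ([], []))
            starts.append(rep.interval.start)
            ends.append(rep.interval.end)
        self.keys: list[str] = list(keys)
        self._groups: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self._chrom_keys: dict[str, list[str]] = {}
        for (chrom, key), (starts, ends) in grouped.items():
            self._groups[(chrom, key)] = (
                np.sort(np.asarray(starts, dtype=np.int64)),
                np.sort(np.asarray(ends, dtype=np.int64)),
            )
            self._chrom_keys.setdefault(chrom, []).append(key)

    def count(self, window_arrays: WindowArrays, mode: str = "pairs") -> dict[str, int]:
        """Count overlaps for pre-grouped windows; all index keys reported."""
        if mode not in ("pairs", "distinct_windows"):
            raise ValueError(f"unknown mode {mode!r} (use 'pairs' or 'distinct_windows')")
        counts = dict.fromkeys(self.keys, 0)
        for chrom, (ws, we) in window_arrays.items():
            for key in self._chrom_keys.get(chrom, ()):
                starts, ends = self._groups[(chrom, key)]
                per_window = (
                    np.searchsorted(starts, we, side="left")
                    - np.searchsorted(ends, ws, side="right")
                )
                if mode == "pairs":
                    counts[key] += int(per_window.sum())
                else:
                    counts[key] += int(np.count_nonzero(per_window))
        return counts


def count_overlaps(
    windows: Sequence[SummitWindow],
    repeats: Iterable[RepeatFeature],
    by: str = "family",
    mode: str = "pairs",
) -> OverlapCounts:
    """Count (window, repeat) overlaps grouped by repeat family or element.

    Overlap requires the same chromosome and >= 1 shared base.  Empty inputs
    yield all-zero counts over the keys present in the annotation.
    """
    index = RepeatIndex(repeats, by=by)
    return OverlapCounts(index.count(windows_to_arrays(windows), mode=mode), by, mode)


def select_peaks(
    peaks: Sequence[Peak],
    fdr_max: float | None = None,
    ef_min: float | None = None,
    combine: str = "or",
) -> list[Peak]:
    """Filter peaks by FDR and/or fold-enrichment thresholds.

    A peak passes the FDR criterion iff its fdr is present and <= fdr_max,
    and the enrichment criterion iff enrichment >= ef_min; the two are
    combined with ``or`` (the convention used for peak-set definitions like
    "FDR = 0 or fold change >= 15") or ``and``.
    """
    if fdr_max is None and ef_min is None:
        raise ValueError("at least one of fdr_max, ef_min must be given")
    if combine not in ("or", "and"):
        raise ValueError(f"unknown combine {combine!r}")

    def keep(p: Peak) -> bool:
        tests = []
        if fdr_max is not None:
            tests.append(p.fdr is not None and p.fdr <= fdr_max)
        if ef_min is not None:
            tests.append(p.enrichment >= ef_min)
        return any(tests) if combine == "or" else all(tests)

    return [p for p in peaks if keep(p)]


def classify_tss_proximity(
    peaks: Sequence[Peak],
    tss: Sequence[tuple[str, int]],
    threshold: int = 5000,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify each peak as TSS-proximal or -distal by summit distance.

    Distance is the minimum |summit - tss| over same-chromosome TSS entries;
    a peak is proximal iff distance <= threshold (default 5 kb).  Peaks on
    chromosomes without any TSS are distal with NaN distance.

    Returns a per-peak table (label, chrom, summit, distance, proximity) and
    summary fractions {"proximal": ..., "distal": ...}.
    """
    if not tss:
        warnings.warn("empty TSS list: every peak classified distal", stacklevel=2)
    positions_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in tss:
        positions_by_chrom.setdefault(chrom, []).append(int(pos))
    tss_by_chrom = {
        c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in positions_by_chrom.items()
    }

    rows = []
    for i, peak in enumerate(peaks):
        positions = tss_by_chrom.get(peak.chrom)
        if positions is None or len(positions) == 0:
            dist = np.nan
            proximal = False
        else:
            j = np.searchsorted(positions, peak.summit)
            candidates = positions[max(0, j - 1): j + 1]
            dist = int(np.min(np.abs(candidates - peak.summit)))
            proximal = dist <= threshold
        rows.append(
            {
                "label": peak.label or f"peak_{i}",
                "chrom": peak.chrom,
                "summit": peak.summit,
                "distance": dist,
                "proximity": "proximal" if proximal else "distal",
            }
        )
    table = pd.DataFrame(
        rows, columns=["label", "chrom", "summit", "distance", "proximity"]
    )
    n = len(table)
    n_prox = int((table["proximity"] == "proximal").sum()) if n else 0
    summary = {
        "proximal": n_prox / n if n else 0.0,
        "distal": (n - n_prox) / n if n else 0.0,
    }
    return table, summary


def extract_summit_sequences(
    peaks: Sequence[Peak],
    genome_fasta: str | Path,
    width: int = 200,
) -> list[SeqRecord]:
    """Extract width-bp sequences centred on peak summits from a FASTA file.

    Windows follow the make_summit_windows centering/clamping rule; each
    record id is ``chrom:start-end`` (0-based half-open).  The default 200 bp
    matches the window used to feed summit regions to motif discovery.
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    genome = Genome([(name, len(seq)) for name, seq in sequences.items()])
    missing = sorted({p.chrom for p in peaks} - set(genome.names))
    if missing:
        raise ValueError(f"chromosomes missing from FASTA: {missing}")
    records = []
    for window in make_summit_windows(peaks, genome, width=width):
        iv = window.interval
        seq = sequences[iv.chrom][iv.start: iv.end]
        records.append(
            SeqRecord(Seq(seq), id=f"{iv.chrom}:{iv.start}-{iv.end}", description="")
        )
    return records
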