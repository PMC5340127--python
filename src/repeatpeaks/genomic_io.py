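"""File formats and elementary sequence utilities.

All genomic coordinates are held 0-based, half-open (BED convention).
Dialects that use other conventions (the MACS 1.4 ``.xls`` peak table is
1-based with the summit stored as an offset from the peak start) are
converted on read and never leak into the rest of the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Genome",
    "Interval",
    "Peak",
    "RepeatFeature",
    "OligoProbe",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_repeat_annotation",
    "write_repeats_bed",
    "read_peaks",
    "write_peaks_bed",
    "reverse_complement",
    "clean_oligo",
    "validate_duplex",
    "stap2_probes",
    "STAP2_PROBE_SEQUENCES",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA_RE = re.compile(r"^[ACGT]+$")


class Genome:
    """Ordered chromosome-name -> length (bp) map.

    Chromosome names are unique and lengths are positive integers; the
    insertion order of the source file is preserved.
    """

    def __init__(self, sizes: Iterable[tuple[str, int]] | dict[str, int]):
        items = sizes.items() if isinstance(sizes, dict) else sizes
        self._sizes: dict[str, int] = {}
        for name, length in items:
            name = str(name)
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}: {length}")
            self._sizes[name] = length

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    @property
    def total_size(self) -> int:
        return sum(self._sizes.values())

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self._sizes.items())

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes

    def __repr__(self) -> str:
        return f"Genome({self._sizes!r})"


@dataclass(frozen=True)
class Interval:
    """A genomic span, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus summit position and caller scores.

    ``enrichment`` is the caller's fold enrichment over input ("ef"); ``fdr``
    is a fraction in [0, 1] or None when the caller reported none.
    """

    interval: Interval
    summit: int
    enrichment: float = 0.0
    fdr: float | None = None
    label: str = ""

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.enrichment < 0:
            raise ValueError("enrichment must be nonnegative")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must be in [0, 1], got {self.fdr}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class RepeatFeature:
    """A RepeatMasker annotation: interval plus element name, class, family."""

    interval: Interval
    rep_name: str
    rep_class: str = ""
    rep_family: str = ""

    def __post_init__(self):
        if not self.rep_name:
            raise ValueError("rep_name must be nonempty")


@dataclass(frozen=True)
class OligoProbe:
    """A double-stranded oligo probe; both strands stored 5'->3'.

    Raw printed sequences may carry modification prefixes ("5'biotin-") and
    typesetting whitespace; these are stripped on construction.
    """

    name: str
    forward: str
    reverse: str = ""

    def __post_init__(self):
        object.__setattr__(self, "forward", clean_oligo(self.forward))
        object.__setattr__(self, "reverse", clean_oligo(self.reverse) if self.reverse else "")
        if not self.forward:
            raise ValueError("forward sequence must be nonempty")


def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a two-column (name, length) tab-separated chromosome-sizes table."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            name, raw_len = fields[0], fields[1]
            try:
                length = int(raw_len)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {raw_len!r}"
                ) from None
            pairs.append((name, length))
    try:
        return Genome(pairs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


# UCSC rmsk full-field dumps carry many columns; only these are consumed.
_RMSK_REQUIRED = ("genoName", "genoStart", "genoEnd", "repName")
_RMSK_OPTIONAL = ("strand", "repClass", "repFamily")


def read_repeat_annotation(path: str | Path, dialect: str = "rmsk_tsv") -> list[RepeatFeature]:
    """Read a repeat annotation.

    ``rmsk_tsv``: a UCSC RepeatMasker table dump with a (possibly
    '#'-prefixed) header row naming at least genoName/genoStart/genoEnd/
    repName; unused columns are ignored.

    ``name_encoded_bed``: BED with the name field either
    ``repName#repClass/repFamily`` or a bare element name (class/family then
    left empty, so such features join element-level but not family-level
    statistics).
    """
    if dialect == "rmsk_tsv":
        return _read_rmsk_tsv(path)
    if dialect == "name_encoded_bed":
        return _read_name_encoded_bed(path)
    raise ValueError(f"unknown repeat-annotation dialect: {dialect!r}")


def _read_rmsk_tsv(path: str | Path) -> list[RepeatFeature]:
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            return []
        header = header_line.lstrip("#").rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in _RMSK_REQUIRED if c not in col]
        if missing:
            raise ValueError(f"{path}: rmsk header missing columns {missing}")
        features = []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            start = int(fields[col["genoStart"]])
            end = int(fields[col["genoEnd"]])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = fields[col["strand"]] if "strand" in col else "."
            features.append(
                RepeatFeature(
                    interval=Interval(
                        fields[col["genoName"]], start, end,
                        strand if strand in ("+", "-") else ".",
                    ),
                    rep_name=fields[col["repName"]],
                    rep_class=fields[col["repClass"]] if "repClass" in col else "",
                    rep_family=fields[col["repFamily"]] if "repFamily" in col else "",
                )
            )
    return features


def _read_name_encoded_bed(path: str | Path) -> list[RepeatFeature]:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need at least 4 BED columns")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            rep_name, rep_class, rep_family = _split_repeat_name(name)
            features.append(
                RepeatFeature(
                    interval=Interval(chrom, start, end, strand),
                    rep_name=rep_name,
                    rep_class=rep_class,
                    rep_family=rep_family,
                )
            )
    return features


def _split_repeat_name(name: str) -> tuple[str, str, str]:
    if "#" not in name:
        return name, "", ""
    rep_name, taxonomy = name.split("#", 1)
    if "/" in taxonomy:
        rep_class, rep_family = taxonomy.split("/", 1)
    else:
        rep_class, rep_family = taxonomy, ""
    return rep_name, rep_class, rep_family


def write_repeats_bed(features: Iterable[RepeatFeature], path: str | Path) -> None:
    """Write repeats as name-encoded BED6 (name = repName#repClass/repFamily)."""
    with open(path, "w") as fh:
        for f in features:
            if f.rep_class or f.rep_family:
                name = f"{f.rep_name}#{f.rep_class}/{f.rep_family}"
            else:
                name = f.rep_name
            iv = f.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_peaks(path: str | Path, dialect: str = "bed_summit") -> list[Peak]:
    """Read a peak table.

    ``bed_summit``: tab-separated ``chrom start end name summit [ef] [fdr]``
    with all coordinates 0-based and the summit absolute.

    ``macs_xls``: a MACS 1.4 peak table ('#' comments, then a header row).
    Start is 1-based, the summit column is an offset from the start, and the
    FDR column is a percentage; all are converted (0-based absolute summit,
    FDR as a fraction).
    """
    if dialect == "bed_summit":
        return _read_bed_summit(path)
    if dialect == "macs_xls":
        return _read_macs_xls(path)
    raise ValueError(f"unknown peak dialect: {dialect!r}")


def _read_bed_summit(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: need >= 5 columns (chrom start end name summit)"
                )
            chrom, start, end, name, summit = (
                fields[0], int(fields[1]), int(fields[2]), fields[3], int(fields[4]),
            )
            ef = float(fields[5]) if len(fields) > 5 and fields[5] != "." else 0.0
            fdr = float(fields[6]) if len(fields) > 6 and fields[6] != "." else None
            try:
                peaks.append(
                    Peak(Interval(chrom, start, end), summit, ef, fdr, label=name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return peaks


def _read_macs_xls(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = {name.strip().lower(): i for i, name in enumerate(fields)}
                required = ("chr", "start", "end", "summit")
                missing = [c for c in required if c not in header]
                if missing:
                    raise ValueError(f"{path}: MACS header missing columns {missing}")
                fdr_col = next(
                    (i for name, i in header.items() if name.startswith("fdr")), None
                )
                ef_col = header.get("fold_enrichment")
                continue
            chrom = fields[header["chr"]]
            start = int(fields[header["start"]]) - 1  # 1-based -> 0-based
            end = int(fields[header["end"]])
            summit = start + int(fields[header["summit"]])  # offset from start
            ef = float(fields[ef_col]) if ef_col is not None else 0.0
            fdr = float(fields[fdr_col]) / 100.0 if fdr_col is not None else None
            try:
                peaks.append(
                    Peak(Interval(chrom, start, end), summit, ef, fdr,
                         label=f"{chrom}:{start}-{end}")
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks in the bed_summit dialect (round-trips with read_peaks)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            name = p.label or f"peak_{i}"
            fdr = "." if p.fdr is None else format(p.fdr, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p.summit}"
                f"\t{p.enrichment:g}\t{fdr}\n"
            )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


_OLIGO_PREFIX = re.compile(r"^(?:5[′'])?\s*(?:biotin)?[-–]?\s*", re.IGNORECASE)
_OLIGO_SUFFIX = re.compile(r"\s*[-–]?\s*3[′']$")


def clean_oligo(raw: str) -> str:
    """Strip modification prefixes/suffixes and whitespace from a printed oligo.

    Chemistry tags like ``5'biotin-`` and trailing ``-3'`` are typography, not
    sequence; internal whitespace from typesetting is removed too.  The result
    must be pure uppercase ACGT.
    """
    s = raw.strip()
    s = _OLIGO_PREFIX.sub("", s)
    s = _OLIGO_SUFFIX.sub("", s)
    s = re.sub(r"\s+", "", s).upper()
    if s and not _DNA_RE.match(s):
        bad = sorted(set(s) - set("ACGT"))
        raise ValueError(f"oligo {raw!r} contains non-ACGT characters after cleaning: {bad}")
    return s


def validate_duplex(probe: OligoProbe) -> dict:
    """Check that a probe's strands anneal into a perfect duplex.

    The duplex is valid iff the reverse oligo is exactly the reverse
    complement of the forward oligo.  Mismatch positions are 1-based along
    the forward strand; a length difference is reported separately.
    """
    if not probe.reverse:
        raise ValueError(f"probe {probe.name!r} has no reverse strand")
    expected = reverse_complement(probe.forward)
    mismatches = [
        i + 1
        for i, (a, b) in enumerate(zip(expected, probe.reverse))
        if a != b
    ]
    length_mismatch = len(probe.forward) != len(probe.reverse)
    return {
        "name": probe.name,
        "valid": not mismatches and not length_mismatch,
        "length_forward": len(probe.forward),
        "length_reverse": len(probe.reverse),
        "mismatch_positions": mismatches,
    }


# EMSA probes covering the two G/C-rich motifs at an intronic STAP2-locus
# ChIP peak (GRCh37 chr19:4,328,490-4,328,689), as printed: forward strands
# carry a 5'-biotin tag, and the long reverse oligo an internal line-break
# space.  clean_oligo() normalises both.
STAP2_PROBE_SEQUENCES: dict[str, tuple[str, str]] = {
    "STAP2_M2": (
        "5′biotin- CGGGTCGGACTCCGCCCCTGCTTCTGA-3′",
        "5′-TCAGAAGCAGGGGCGGAGTCCGACCCG-3′",
    ),
    "STAP2_M1": (
        "5′biotin-CTGACCACGCCCCCGCGCCCACCCTCTT-3′",
        "5′-AAGAGGGTGGGCGCGGGGGCGTGGTCAG-3′",
    ),
    "STAP2_M2+M1": (
        "5′biotin-CGGGTCGGACTCCGCCCCTGCTTCTGACCACGCCCCCGCGCCCACCCTCTT-3′",
        "5′-AAGAGGGTGGGCGCGGGGGCGTGG TCAGAAGCAGGGGCGGAGTCCGACCCG-3′",
    ),
}


def stap2_probes() -> list[OligoProbe]:
    """The three published STAP2 EMSA probes as cleaned OligoProbe objects."""
    return [
        OligoProbe(name, fwd, rev)
        for name, (fwd, rev) in STAP2_PROBE_SEQUENCES.items()
    ]
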