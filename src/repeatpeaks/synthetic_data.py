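"""Ground-truth fixture generators for every pipeline stage.

A small multi-chromosome genome (default: three chromosomes of 1 Mb, 500 kb
and 250 kb — large enough for stable Monte-Carlo nulls, small enough for
seconds-scale tests) is annotated with non-overlapping repeat features laid
down to family-level target coverages.  Peak sets plant a chosen fraction of
summits inside (or, in exclusion mode, strictly outside) one family's
footprint, giving known enrichment or depletion for the statistics to
recover.  Toy expression tables and canonical C2H2 zinc-finger proteins
carry their ground truth alongside.

Everything is bit-reproducible from its seed, and writers emit the same text
formats the readers consume so fixtures exercise I/O end to end.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from repeatpeaks.fingerprint import QUADRUPLET_OFFSETS, ZincFinger, scan_c2h2
from repeatpeaks.genomic_io import (
    Genome,
    Interval,
    Peak,
    RepeatFeature,
    write_chrom_sizes,
    write_peaks_bed,
    write_repeats_bed,
)

__all__ = [
    "FamilySpec",
    "PlantingRule",
    "SimulationSpec",
    "default_genome",
    "simulate_repeat_annotation",
    "simulate_peaks",
    "simulate_zf_protein",
    "simulate_expression_table",
    "simulate_genome_sequences",
    "write_fixture_dir",
]

_MIN_FEATURE_LEN = 20
# filler alphabet for zinc-finger scaffolds: every residue except C, H (and X)
_ZF_FILLER = "ADEFGIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilySpec:
    """One repeat family: name, element names cycled round-robin, target
    genome coverage fraction, and mean feature length (bp)."""

    name: str
    elements: tuple[str, ...]
    coverage: float
    mean_length: int = 500

    def __post_init__(self):
        if not (0.0 < self.coverage < 1.0):
            raise ValueError("coverage must be in (0, 1)")
        if not self.elements:
            raise ValueError("family needs at least one element name")
        if self.mean_length < _MIN_FEATURE_LEN:
            raise ValueError(f"mean_length must be >= {_MIN_FEATURE_LEN}")

    @property
    def rep_class(self) -> str:
        """Class part of a 'Class/Family' name, empty for a bare family name."""
        return self.name.split("/")[0] if "/" in self.name else ""

    @property
    def rep_family(self) -> str:
        return self.name.split("/")[-1]


@dataclass(frozen=True)
class PlantingRule:
    """Where peak summits go relative to one family.

    ``fraction`` of summits are placed uniformly inside the family's
    features (mode 'include'); the rest are uniform over the genome.  Mode
    'exclude' instead places every summit uniformly over the family's
    complement.
    """

    family: str
    fraction: float = 0.0
    mode: str = "include"

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if self.mode not in ("include", "exclude"):
            raise ValueError(f"unknown planting mode {self.mode!r}")


@dataclass(frozen=True)
class SimulationSpec:
    genome: Genome = field(default_factory=lambda: default_genome())
    families: tuple[FamilySpec, ...] = ()
    n_peaks: int = 50
    peak_halfwidth: int = 100
    planting: PlantingRule | None = None
    seed: int = 0

    def __post_init__(self):
        total = sum(f.coverage for f in self.families)
        if total >= 1.0:
            raise ValueError(f"family coverages sum to {total:.2f} >= 1")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")


def default_genome() -> Genome:
    return Genome([("chrS1", 1_000_000), ("chrS2", 500_000), ("chrS3", 250_000)])


class _Occupancy:
    """Per-chromosome sorted non-overlapping interval bookkeeping."""

    def __init__(self, genome: Genome):
        self._starts = {c: [] for c in genome.names}
        self._ends = {c: [] for c in genome.names}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        starts, ends = self._starts[chrom], self._ends[chrom]
        i = bisect.bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            return False
        return not (i < len(starts) and starts[i] < end)

    def add(self, chrom: str, start: int, end: int) -> None:
        i = bisect.bisect_right(self._starts[chrom], start)
        self._starts[chrom].insert(i, start)
        self._ends[chrom].insert(i, end)


def _weighted_chrom(rng: np.random.Generator, genome: Genome, min_len: int) -> str:
    names = [c for c in genome.names if genome[c] >= min_len]
    if not names:
        raise ValueError(f"no chromosome can hold a feature of length {min_len}")
    weights = np.asarray([genome[c] for c in names], dtype=float)
    return names[rng.choice(len(names), p=weights / weights.sum())]


def simulate_repeat_annotation(spec: SimulationSpec) -> list[RepeatFeature]:
    """Place non-overlapping repeat features to each family's target coverage.

    Placement is rejection sampling (uniform position, reject on overlap with
    anything already placed); each family stops within 5% relative of its
    coverage target, well inside the 10% contract.  Raises when targets are
    too dense to satisfy.
    """
    rng = np.random.default_rng([spec.seed, 101])
    total_bp = spec.genome.total_size
    occupancy = _Occupancy(spec.genome)
    features: list[RepeatFeature] = []
    for family in spec.families:
        target = family.coverage * total_bp
        placed = 0.0
        element_cursor = 0
        attempts = 0
        max_attempts = 200 * max(1, int(target / family.mean_length)) + 10_000
        while placed < 0.95 * target:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"cannot reach coverage {family.coverage} for family "
                    f"{family.name!r}: annotation too dense"
                )
            length = int(rng.uniform(0.5, 1.5) * family.mean_length)
            length = max(length, _MIN_FEATURE_LEN)
            if placed + length > 1.05 * target:
                length = int(target - placed)
                if length < _MIN_FEATURE_LEN:
                    break
            chrom = _weighted_chrom(rng, spec.genome, length)
            start = int(rng.integers(0, spec.genome[chrom] - length + 1))
            end = start + length
            if not occupancy.is_free(chrom, start, end):
                continue
            occupancy.add(chrom, start, end)
            features.append(
                RepeatFeature(
                    interval=Interval(chrom, start, end),
                    rep_name=family.elements[element_cursor % len(family.elements)],
                    rep_class=family.rep_class,
                    rep_family=family.rep_family,
                )
            )
            element_cursor += 1
            placed += length
    features.sort(key=lambda f: (f.interval.chrom, f.interval.start))
    return features


def _family_footprint(
    annotation: Sequence[RepeatFeature], family: str
) -> list[RepeatFeature]:
    family = family.split("/")[-1]
    feats = [f for f in annotation if f.rep_family == family]
    if not feats:
        raise ValueError(f"planting family {family!r} absent from annotation")
    return feats


def _uniform_genome_position(rng: np.random.Generator, genome: Genome) -> tuple[str, int]:
    lengths = np.asarray([genome[c] for c in genome.names], dtype=float)
    ci = rng.choice(len(lengths), p=lengths / lengths.sum())
    chrom = genome.names[ci]
    return chrom, int(rng.integers(0, genome[chrom]))


def _position_in_family(
    rng: np.random.Generator, feats: Sequence[RepeatFeature]
) -> tuple[str, int]:
    lengths = np.asarray([len(f.interval) for f in feats], dtype=float)
    fi = rng.choice(len(feats), p=lengths / lengths.sum())
    iv = feats[fi].interval
    return iv.chrom, int(rng.integers(iv.start, iv.end))


def _inside_family(feats_by_chrom, chrom: str, pos: int) -> bool:
    entry = feats_by_chrom.get(chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = bisect.bisect_right(starts, pos)
    return i > 0 and ends[i - 1] > pos


def simulate_peaks(
    spec: SimulationSpec, annotation: Sequence[RepeatFeature]
) -> list[Peak]:
    """Draw a peak set under the spec's planting rule.

    Include mode: each summit lands inside the planting family's footprint
    with probability ``fraction`` (uniform within the footprint), otherwise
    uniform over the genome.  Exclude mode: every summit is uniform over the
    family's complement.  Peak intervals are summit +/- peak_halfwidth
    clamped to the chromosome; fold enrichment is log-normal (median 20,
    sigma 0.5 on the log scale) and FDR is 0, so default peak selection
    keeps everything.
    """
    rng = np.random.default_rng([spec.seed, 202])
    rule = spec.planting or PlantingRule(family="", fraction=0.0)
    feats = _family_footprint(annotation, rule.family) if rule.family else []
    feats_by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for f in feats:
        starts, ends = feats_by_chrom.setdefault(f.interval.chrom, ([], []))
        starts.append(f.interval.start)
        ends.append(f.interval.end)

    footprint = sum(len(f.interval) for f in feats)
    if rule.mode == "exclude" and footprint >= spec.genome.total_size:
        raise ValueError("cannot exclude a family covering the whole genome")

    peaks = []
    for i in range(spec.n_peaks):
        if rule.mode == "exclude" and rule.family:
            while True:
                chrom, summit = _uniform_genome_position(rng, spec.genome)
                if not _inside_family(feats_by_chrom, chrom, summit):
                    break
        elif rule.family and rng.random() < rule.fraction:
            chrom, summit = _position_in_family(rng, feats)
        else:
            chrom, summit = _uniform_genome_position(rng, spec.genome)
        start = max(0, summit - spec.peak_halfwidth)
        end = min(spec.genome[chrom], summit + spec.peak_halfwidth)
        ef = float(rng.lognormal(mean=np.log(20.0), sigma=0.5))
        peaks.append(
            Peak(Interval(chrom, start, end), summit, ef, fdr=0.0, label=f"peak_{i}")
        )
    return peaks


def simulate_zf_protein(
    n_fingers: int,
    quadruplets: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[str, list[ZincFinger]]:
    """Build a protein with ``n_fingers`` canonical C2H2 fingers.

    Fingers follow C-xx-C-x(12)-H-xxx-H with the given 4-letter quadruplets
    installed at the DNA-contact offsets; linkers and flanks never contain C
    or H, so a scan finds exactly the planted fingers.  Returns the sequence
    and the ground-truth finger list (absolute coordinates, N->C).
    """
    rng = np.random.default_rng([seed, 303])
    if quadruplets is None:
        quadruplets = [
            "".join(rng.choice(list(_ZF_FILLER), size=4)) for _ in range(n_fingers)
        ]
    if len(quadruplets) != n_fingers:
        raise ValueError("need one quadruplet per finger")
    for q in quadruplets:
        if len(q) != 4:
            raise ValueError(f"quadruplet {q!r} must have 4 residues")
        if not set(q) <= set(_ZF_FILLER) | {"C", "H"}:
            raise ValueError(f"quadruplet {q!r} has letters outside the amino-acid alphabet")

    def filler(n: int) -> str:
        return "".join(rng.choice(list(_ZF_FILLER), size=n))

    parts = [filler(8)]  # N-terminal flank
    fingers: list[ZincFinger] = []
    pos = len(parts[0])
    for q in quadruplets:
        x12 = list(filler(12))
        # offsets are relative to the first His, which sits right after x12
        for off, letter in zip(QUADRUPLET_OFFSETS, q):
            x12[12 + off] = letter
        finger_seq = "C" + filler(2) + "C" + "".join(x12) + "H" + filler(3) + "H"
        start = pos
        his_index = start + 1 + 2 + 1 + 12
        fingers.append(ZincFinger(start, start + len(finger_seq), his_index, q))
        parts.append(finger_seq)
        pos += len(finger_seq)
        linker = "TGEKP"
        parts.append(linker)
        pos += len(linker)
    parts.append(filler(8))  # C-terminal flank
    sequence = "".join(parts)
    # structural self-check: contact-position C/H letters are tolerated only
    # when they leave the canonical pattern unambiguous
    found = scan_c2h2(sequence)
    if [(f.start, f.end, f.quadruplet) for f in found] != [
        (f.start, f.end, f.quadruplet) for f in fingers
    ]:
        raise ValueError(
            "planted quadruplets corrupt the canonical C2H2 pattern "
            "(scan does not recover the planted fingers)"
        )
    return sequence, fingers


def simulate_expression_table(
    n_genes: int = 1000,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    effect: float = 4.0,
    noise_sigma: float = 0.2,
    n_samples: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Toy expression table with planted up/down genes and a truth column.

    Null genes: log2 fold change ~ N(0, noise_sigma), p_raw uniform.
    Affected genes: fold change ``effect`` (or 1/effect) with mild log noise,
    p_raw log-uniform in [1e-8, 1e-4].  FPKM values are log-normal across
    ``n_samples`` samples with gene-level medians spanning well below and
    above 1, so the expression filter has genuine work to do.
    """
    if frac_up + frac_down > 1.0:
        raise ValueError("frac_up + frac_down must be <= 1")
    rng = np.random.default_rng([seed, 404])
    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    truth = ["up"] * n_up + ["down"] * n_down + ["null"] * (n_genes - n_up - n_down)

    log2fc = rng.normal(0.0, noise_sigma, size=n_genes)
    log2fc[: n_up] = np.log2(effect) + rng.normal(0.0, 0.1, size=n_up)
    log2fc[n_up: n_up + n_down] = -np.log2(effect) + rng.normal(0.0, 0.1, size=n_down)
    p_raw = rng.uniform(0.0, 1.0, size=n_genes)
    p_raw[: n_up + n_down] = 10.0 ** rng.uniform(-8, -4, size=n_up + n_down)

    base = rng.lognormal(mean=0.5, sigma=1.5, size=n_genes)
    table = pd.DataFrame(
        {
            "gene_id": [f"gene_{i:05d}" for i in range(n_genes)],
            "fold_change": np.power(2.0, log2fc),
            "p_raw": p_raw,
        }
    )
    for s in range(n_samples):
        table[f"fpkm_s{s + 1}"] = base * rng.lognormal(0.0, 0.2, size=n_genes)
    table["truth"] = truth
    return table


def simulate_genome_sequences(genome: Genome, seed: int = 0) -> dict[str, str]:
    """Random ACGT sequence for every chromosome (for window extraction)."""
    rng = np.random.default_rng([seed, 505])
    bases = np.array(list("ACGT"))
    return {
        name: "".join(rng.choice(bases, size=length))
        for name, length in genome.items()
    }


def write_fixture_dir(spec: SimulationSpec, outdir: str | Path, fasta: bool = False) -> dict[str, Path]:
    """Materialise a complete fixture directory in the package's file formats.

    Writes chrom.sizes, repeats (name-encoded BED), peaks (bed_summit),
    an expression table, and optionally the genome FASTA.  Returns the path
    of each written file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_repeat_annotation(spec)
    peaks = simulate_peaks(spec, annotation)
    paths = {
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "repeats": outdir / "repeats.bed",
        "peaks": outdir / "peaks.bed",
        "expression": outdir / "expression.tsv",
    }
    write_chrom_sizes(spec.genome, paths["chrom_sizes"])
    write_repeats_bed(annotation, paths["repeats"])
    write_peaks_bed(peaks, paths["peaks"])
    simulate_expression_table(seed=spec.seed).to_csv(
        paths["expression"], sep="\t", index=False
    )
    if fasta:
        paths["fasta"] = outdir / "genome.fa"
        with open(paths["fasta"], "w") as fh:
            for name, seq in simulate_genome_sequences(spec.genome, spec.seed).items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i: i + 80] + "\n")
    return paths
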