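"""C2H2 zinc-finger detection and DNA-contact fingerprints.

A canonical C2H2 finger matches C-x(2,4)-C-x(12)-H-x(3,5)-H.  The four
residues that contact DNA sit at helix positions -1, 2, 3 and 6 relative to
the recognition alpha-helix; taking the first conserved histidine as helix
position 7, they lie at offsets -7, -5, -4 and -1 from it.  The ordered
quadruplets over a protein's finger array form its "fingerprint", and
fingerprints of different proteins are compared with the fingers aligned
from the C-terminus backwards (C->N), since C-terminal fingers of related
proteins tend to be the conserved anchor of the array.

On the classic Zif268 finger 1 (``...CPVESCDRRFSRSDELTRHIRIH...``) this
convention extracts R, D, E, R — its textbook DNA-contact residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

__all__ = ["ZincFinger", "Fingerprint", "scan_c2h2", "compare_fingerprints"]

# lazy spacer quantifiers: leftmost match with shortest admissible spacers;
# the x(12) group ends exactly at the first conserved histidine
_C2H2_RE = re.compile(r"C.{2,4}?C(.{12})H.{3,5}?H")
_AA = set("ACDEFGHIKLMNPQRSTVWY")
# offsets of helix positions -1, 2, 3, 6 from the first conserved histidine
QUADRUPLET_OFFSETS = (-7, -5, -4, -1)


@dataclass(frozen=True)
class ZincFinger:
    """One matched finger: span, first-histidine index, contact quadruplet."""

    start: int
    end: int
    first_his_index: int
    quadruplet: str

    def __post_init__(self):
        if len(self.quadruplet) != 4:
            raise ValueError("quadruplet must have exactly 4 residues")
        if not (self.start <= self.first_his_index < self.end):
            raise ValueError("first histidine outside finger span")


@dataclass(frozen=True)
class Fingerprint:
    """A protein's ordered finger list (stored N->C; compared C->N)."""

    protein_id: str
    fingers: tuple[ZincFinger, ...]

    def __post_init__(self):
        for a, b in zip(self.fingers, self.fingers[1:]):
            if b.start < a.end:
                raise ValueError("fingers must be non-overlapping and sorted")

    @property
    def quadruplets(self) -> list[str]:
        return [f.quadruplet for f in self.fingers]


def scan_c2h2(protein: str) -> list[ZincFinger]:
    """Find non-overlapping canonical C2H2 fingers, left to right.

    The scan takes the leftmost match, then resumes after it, with spacer
    lengths resolved shortest-first — a deterministic greedy-leftmost rule.
    'X' is tolerated in the sequence but must not land on an extracted
    contact position.
    """
    protein = protein.upper()
    bad = set(protein) - _AA - {"X"}
    if bad:
        raise ValueError(f"invalid amino-acid letters: {sorted(bad)}")
    fingers = []
    pos = 0
    while True:
        match = _C2H2_RE.search(protein, pos)
        if match is None:
            break
        start, end = match.span()
        his_index = match.end(1)  # first conserved His follows the x(12) block
        assert protein[his_index] == "H"
        quadruplet = "".join(protein[his_index + off] for off in QUADRUPLET_OFFSETS)
        if "X" in quadruplet:
            raise ValueError(
                f"ambiguous residue 'X' at a DNA-contact position (finger at {start})"
            )
        fingers.append(ZincFinger(start, end, his_index, quadruplet))
        pos = end
    return fingers


def compare_fingerprints(a: Fingerprint, b: Fingerprint) -> dict:
    """Compare two fingerprints with fingers aligned C->N.

    Fingers are paired from the C-terminal end backwards; extra N-terminal
    fingers of the longer array are unpaired.  Each pair contributes the
    Hamming distance over its 4 contact positions; ``total`` sums the paired
    distances.
    """
    n_pairs = min(len(a.fingers), len(b.fingers))
    pairs = []
    total = 0
    for k in range(1, n_pairs + 1):
        fa = a.fingers[-k]
        fb = b.fingers[-k]
        dist = sum(x != y for x, y in zip(fa.quadruplet, fb.quadruplet))
        total += dist
        pairs.append(
            {
                "index_a": len(a.fingers) - k,
                "index_b": len(b.fingers) - k,
                "quadruplet_a": fa.quadruplet,
                "quadruplet_b": fb.quadruplet,
                "distance": dist,
            }
        )
    pairs.reverse()  # report N->C for readability
    return {
        "pairs": pairs,
        "unpaired_a": list(range(len(a.fingers) - n_pairs)),
        "unpaired_b": list(range(len(b.fingers) - n_pairs)),
        "total": total,
    }


def fingerprint_from_sequence(protein_id: str, protein: str) -> Fingerprint:
    """Scan a protein and wrap the result as a Fingerprint."""
    return Fingerprint(protein_id, tuple(scan_c2h2(protein)))


def fingerprint_table(fingerprints: Sequence[Fingerprint]) -> list[dict]:
    """Flatten fingerprints into report rows (one row per finger, N->C)."""
    rows = []
    for fp in fingerprints:
        for i, finger in enumerate(fp.fingers):
            rows.append(
                {
                    "protein": fp.protein_id,
                    "finger": i,
                    "start": finger.start,
                    "end": finger.end,
                    "quadruplet": finger.quadruplet,
                }
            )
    return rows
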