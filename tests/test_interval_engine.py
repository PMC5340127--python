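"""Summit windows, overlap counting, peak selection, TSS proximity, extraction."""

import shutil
import subprocess

import numpy as np
import pytest

from repeatpeaks.genomic_io import Genome, Interval, Peak, RepeatFeature
from repeatpeaks.interval_engine import (
    SummitWindow,
    classify_tss_proximity,
    count_overlaps,
    extract_summit_sequences,
    make_summit_windows,
    select_peaks,
)

from conftest import brute_force_overlap_counts, random_interval_fixture


def peak_at(summit, chrom="chr1", ef=10.0, fdr=0.0):
    return Peak(Interval(chrom, max(0, summit - 100), summit + 100), summit, ef, fdr)


def wrap(intervals):
    return [SummitWindow(iv, None) for iv in intervals]


class TestSummitWindows:
    @pytest.mark.parametrize(
        "summit,width,expected",
        [
            (1000, 100, (950, 1050)),  # centred
            (20, 100, (0, 70)),  # clamped at the chromosome start
            (1000, 101, (950, 1051)),  # floor(width/2) centering
        ],
    )
    def test_centering_and_clamping(self, summit, width, expected):
        genome = Genome([("chr1", 10_000)])
        (window,) = make_summit_windows([peak_at(summit)], genome, width=width)
        assert (window.interval.start, window.interval.end) == expected

    def test_clamping_at_chromosome_end(self):
        genome = Genome([("chr1", 1030)])
        (window,) = make_summit_windows([peak_at(1000)], genome, width=100)
        assert (window.interval.start, window.interval.end) == (950, 1030)

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="chrM"):
            make_summit_windows([peak_at(500, chrom="chrM")], Genome([("chr1", 1000)]))


class TestCountOverlaps:
    @pytest.fixture
    def spec_example(self):
        windows = wrap([Interval("chrA", 0, 100), Interval("chrA", 200, 300)])
        repeats = [
            RepeatFeature(Interval("chrA", 90, 150), "AluSx", "SINE", "Alu"),
            RepeatFeature(Interval("chrA", 210, 220), "AluY", "SINE", "Alu"),
            RepeatFeature(Interval("chrA", 250, 260), "MIRb", "SINE", "MIR"),
        ]
        return windows, repeats

    def test_pairs_mode_hand_enumeration(self, spec_example):
        windows, repeats = spec_example
        counts = count_overlaps(windows, repeats, by="family", mode="pairs")
        assert counts.counts == {"Alu": 2, "MIR": 1}

    def test_distinct_windows_mode_hand_enumeration(self, spec_example):
        windows, repeats = spec_example
        counts = count_overlaps(windows, repeats, by="family", mode="distinct_windows")
        assert counts.counts == {"Alu": 2, "MIR": 1}

    def test_distinct_collapses_multiple_hits_in_one_window(self):
        windows = wrap([Interval("chrA", 0, 300)])
        repeats = [
            RepeatFeature(Interval("chrA", 10, 20), "AluSx", "SINE", "Alu"),
            RepeatFeature(Interval("chrA", 30, 40), "AluY", "SINE", "Alu"),
        ]
        assert count_overlaps(windows, repeats, mode="pairs")["Alu"] == 2
        assert count_overlaps(windows, repeats, mode="distinct_windows")["Alu"] == 1

    def test_different_chromosomes_never_overlap(self):
        windows = wrap([Interval("chrA", 0, 100)])
        repeats = [RepeatFeature(Interval("chrB", 0, 100), "AluSx", "SINE", "Alu")]
        assert count_overlaps(windows, repeats)["Alu"] == 0

    def test_half_open_touching_intervals_do_not_overlap(self):
        windows = wrap([Interval("chrA", 0, 100)])
        repeats = [RepeatFeature(Interval("chrA", 100, 200), "AluSx", "SINE", "Alu")]
        assert count_overlaps(windows, repeats)["Alu"] == 0

    @pytest.mark.parametrize("by", ["family", "element"])
    @pytest.mark.parametrize("mode", ["pairs", "distinct_windows"])
    def test_matches_brute_force_on_random_fixtures(self, by, mode):
        rng = np.random.default_rng(42)
        for _ in range(25):
            ivs, repeats = random_interval_fixture(
                rng, int(rng.integers(0, 120)), int(rng.integers(0, 120))
            )
            windows = wrap(ivs)
            expected = brute_force_overlap_counts(windows, repeats, by, mode)
            got = count_overlaps(windows, repeats, by=by, mode=mode).counts
            assert got == expected

    def test_invariant_under_ordering_and_chromosome_renaming(self):
        rng = np.random.default_rng(7)
        ivs, repeats = random_interval_fixture(rng, 60, 60)
        base = count_overlaps(wrap(ivs), repeats).counts
        perm = rng.permutation(len(ivs))
        shuffled = count_overlaps(wrap([ivs[i] for i in perm]), repeats[::-1]).counts
        assert shuffled == base
        renamed_ivs = [Interval("scaf_" + iv.chrom, iv.start, iv.end) for iv in ivs]
        renamed_reps = [
            RepeatFeature(
                Interval("scaf_" + r.interval.chrom, r.interval.start, r.interval.end),
                r.rep_name, r.rep_class, r.rep_family,
            )
            for r in repeats
        ]
        assert count_overlaps(wrap(renamed_ivs), renamed_reps).counts == base

    def test_distinct_counts_never_exceed_pairs_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ivs, repeats = random_interval_fixture(rng, 80, 80)
            pairs = count_overlaps(wrap(ivs), repeats, mode="pairs").counts
            distinct = count_overlaps(wrap(ivs), repeats, mode="distinct_windows").counts
            assert all(distinct[k] <= pairs[k] for k in pairs)

    def test_empty_inputs_give_zero_counts(self):
        assert count_overlaps([], [], by="family").counts == {}
        repeats = [RepeatFeature(Interval("chrA", 0, 10), "AluSx", "SINE", "Alu")]
        assert count_overlaps([], repeats).counts == {"Alu": 0}

    def test_agrees_with_bedtools_intersect(self, tmp_path):
        """Independent cross-check against the interval tool the field uses."""
        if shutil.which("bedtools") is None:
            pytest.fail("bedtools not available for the cross-check")
        rng = np.random.default_rng(99)
        ivs, repeats = random_interval_fixture(rng, 150, 150)
        a = tmp_path / "windows.bed"
        b = tmp_path / "repeats.bed"
        a.write_text("".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in ivs))
        b.write_text(
            "".join(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.rep_family}\n"
                for r in repeats
            )
        )
        out = subprocess.run(
            ["bedtools", "intersect", "-a", str(a), "-b", str(b), "-wa", "-wb"],
            capture_output=True, text=True, check=True,
        )
        bedtools_counts = {}
        for line in out.stdout.splitlines():
            family = line.split("\t")[-1]
            bedtools_counts[family] = bedtools_counts.get(family, 0) + 1
        ours = {
            k: v
            for k, v in count_overlaps(wrap(ivs), repeats, mode="pairs").counts.items()
            if v
        }
        assert ours == bedtools_counts


class TestSelectPeaks:
    @pytest.fixture
    def peaks(self):
        return [
            Peak(Interval("chr1", 0, 100), 50, enrichment=5.0, fdr=0.0),
            Peak(Interval("chr1", 200, 300), 250, enrichment=20.0, fdr=0.01),
            Peak(Interval("chr1", 400, 500), 450, enrichment=10.0, fdr=0.01),
        ]

    def test_fdr_or_enrichment_rule(self, peaks):
        assert len(select_peaks(peaks, fdr_max=0.0, ef_min=15.0, combine="or")) == 2

    def test_single_fdr_criterion(self, peaks):
        assert len(select_peaks(peaks, fdr_max=0.0)) == 1

    def test_missing_fdr_fails_the_fdr_criterion(self):
        peak = Peak(Interval("chr1", 0, 100), 50, enrichment=20.0, fdr=None)
        assert select_peaks([peak], fdr_max=0.0) == []
        assert select_peaks([peak], fdr_max=0.0, ef_min=15.0, combine="or") == [peak]

    def test_or_is_superset_of_each_criterion(self, peaks):
        both = set(map(id, select_peaks(peaks, fdr_max=0.0, ef_min=15.0, combine="or")))
        assert set(map(id, select_peaks(peaks, fdr_max=0.0))) <= both
        assert set(map(id, select_peaks(peaks, ef_min=15.0))) <= both

    def test_empty_input_and_no_criteria(self, peaks):
        assert select_peaks([], fdr_max=0.0) == []
        with pytest.raises(ValueError):
            select_peaks(peaks)


class TestTssProximity:
    def test_boundary_cases(self):
        genome_peaks = [peak_at(1000), peak_at(1000, chrom="chr2")]
        table, _ = classify_tss_proximity(genome_peaks, [("chr1", 1000), ("chr2", 6001)])
        assert table.loc[0, "distance"] == 0 and table.loc[0, "proximity"] == "proximal"
        assert table.loc[1, "distance"] == 5001 and table.loc[1, "proximity"] == "distal"

    def test_exact_threshold_is_proximal(self):
        table, _ = classify_tss_proximity([peak_at(1000)], [("chr1", 6000)])
        assert table.loc[0, "proximity"] == "proximal"

    def test_summary_fractions(self):
        peaks = [peak_at(100), peak_at(9000)]
        _, summary = classify_tss_proximity(peaks, [("chr1", 150)])
        assert summary == {"proximal": 0.5, "distal": 0.5}

    def test_tss_free_chromosome_is_distal_with_nan_distance(self):
        table, _ = classify_tss_proximity([peak_at(500, chrom="chrY")], [("chr1", 0)])
        assert table.loc[0, "proximity"] == "distal"
        assert np.isnan(table.loc[0, "distance"])

    def test_empty_tss_warns_and_classifies_all_distal(self):
        with pytest.warns(UserWarning, match="empty TSS"):
            table, summary = classify_tss_proximity([peak_at(500)], [])
        assert (table["proximity"] == "distal").all()
        assert summary["distal"] == 1.0


class TestExtractSummitSequences:
    @pytest.fixture
    def fasta(self, tmp_path):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        path = tmp_path / "genome.fa"
        path.write_text(f">chr1\n{seq}\n")
        return path, seq

    def test_window_slicing_matches_hand_slices(self, fasta):
        path, seq = fasta
        rng = np.random.default_rng(6)
        summits = [int(s) for s in rng.integers(0, 1000, size=50)]
        peaks = [
            Peak(Interval("chr1", 0, 1000), s, label=f"p{i}")
            for i, s in enumerate(summits)
        ]
        records = extract_summit_sequences(peaks, path, width=200)
        for summit, rec in zip(summits, records):
            start = max(0, summit - 100)
            end = min(1000, summit - 100 + 200)
            assert str(rec.seq) == seq[start:end]
            assert rec.id == f"chr1:{start}-{end}"

    def test_clamped_window_at_origin(self, fasta):
        path, seq = fasta
        (rec,) = extract_summit_sequences([Peak(Interval("chr1", 0, 1000), 100)], path)
        assert str(rec.seq) == seq[0:200]
        assert len(rec.seq) == 200

    def test_missing_chromosome_is_named_in_error(self, fasta):
        path, _ = fasta
        peak = Peak(Interval("chr9", 0, 1000), 100)
        with pytest.raises(ValueError, match="chr9"):
            extract_summit_sequences([peak], path)
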