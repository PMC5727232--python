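"""Window construction, promoter filtering, exclusion, baseline sampling
and sequence extraction."""

import numpy as np
import pytest
from scipy import stats

from fivegc.intervals import GenomicInterval, RegionSet, TSSRecord
from fivegc.io import (
    read_bed,
    read_chrom_sizes,
    read_tss,
    write_bed,
    write_narrowpeak,
)
from fivegc.regions import (
    center_windows,
    exclude_overlapping,
    extract_sequences,
    promoter_filter,
    sample_baseline,
)

SIZES = {"chrA": 100_000, "chrB": 50_000}


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestCenterWindows:
    def test_midpoint_window(self):
        out = center_windows([iv("chrA", 1000, 1300)], SIZES, width=200)
        assert [(r.start, r.end) for r in out] == [(1050, 1250)]

    def test_summit_used_only_when_enabled(self):
        peak = iv("chrA", 1000, 1300, summit_offset=10)
        (mid,) = center_windows([peak], SIZES, width=200)
        (sum_,) = center_windows([peak], SIZES, width=200, use_summit=True)
        assert (mid.start, mid.end) == (1050, 1250)
        assert (sum_.start, sum_.end) == (910, 1110)

    def test_edge_windows_dropped_not_clipped(self):
        out = center_windows(
            [iv("chrA", 0, 50), iv("chrA", 99_990, 100_000)], SIZES, width=200
        )
        assert len(out) == 0

    def test_duplicates_removed_first_order_kept(self):
        peaks = [iv("chrA", 1000, 1300, name="a"), iv("chrA", 1000, 1300, name="b"),
                 iv("chrA", 500, 700, name="c")]
        out = center_windows(peaks, SIZES, width=200)
        assert [r.name for r in out] == ["a", "c"]

    def test_missing_chrom_size_rejected(self):
        with pytest.raises(KeyError, match="chrZ"):
            center_windows([iv("chrZ", 100, 400)], SIZES)

    def test_window_center_equals_peak_center(self, rng):
        peaks = [
            iv("chrA", int(s), int(s + rng.integers(100, 600)))
            for s in rng.integers(1000, 90_000, 50)
        ]
        for peak, win in zip(peaks, center_windows(peaks, SIZES, width=200)):
            assert abs(win.center - peak.center) <= 1


class TestPromoterFilter:
    TSS = [TSSRecord("chrA", 10_000, "+", "gpos"),
           TSSRecord("chrB", 10_000, "-", "gneg")]

    def windows(self, *centers, chrom="chrA"):
        return RegionSet(
            [iv(chrom, c - 100, c + 100) for c in centers], width=200
        )

    def test_upstream_kept_downstream_dropped(self):
        # center 600 bp upstream of a + strand TSS is promoter-proximal
        out = promoter_filter(self.windows(9_400), self.TSS)
        assert len(out) == 1
        # 1100 bp upstream exceeds the limit; 600 bp downstream is not
        # upstream at all
        assert len(promoter_filter(self.windows(8_900), self.TSS)) == 0
        assert len(promoter_filter(self.windows(10_600), self.TSS)) == 0

    def test_minus_strand_mirrored(self):
        # for a - strand TSS at p, upstream means positions > p
        out = promoter_filter(self.windows(10_600, chrom="chrB"), self.TSS)
        assert len(out) == 1
        assert len(promoter_filter(self.windows(9_400, chrom="chrB"), self.TSS)) == 0

    def test_symmetric_superset_of_upstream(self, rng):
        centers = rng.integers(8_000, 12_000, 200)
        wins = self.windows(*[int(c) for c in centers])
        up = promoter_filter(wins, self.TSS, mode="upstream_only")
        sym = promoter_filter(wins, self.TSS, mode="symmetric")
        up_keys = {(r.chrom, r.start) for r in up}
        sym_keys = {(r.chrom, r.start) for r in sym}
        assert up_keys <= sym_keys

    def test_boundary_inclusive(self):
        assert len(promoter_filter(self.windows(9_000), self.TSS)) == 1
        assert len(promoter_filter(self.windows(10_000), self.TSS)) == 1

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError, match="TSS"):
            promoter_filter(self.windows(9_400), [])

    def test_any_tss_suffices(self):
        tss = self.TSS + [TSSRecord("chrA", 50_000, "+", "g2")]
        out = promoter_filter(self.windows(9_400, 49_500), tss)
        assert len(out) == 2


class TestExcludeOverlapping:
    REGIONS = RegionSet([iv("chrA", 100, 300)], width=200)

    def test_one_bp_overlap_removes(self):
        assert len(exclude_overlapping(self.REGIONS, [iv("chrA", 299, 400)])) == 0

    def test_half_open_abutment_kept(self):
        assert len(exclude_overlapping(self.REGIONS, [iv("chrA", 300, 400)])) == 1

    def test_empty_other_is_identity(self):
        assert len(exclude_overlapping(self.REGIONS, [])) == 1

    def test_monotone_in_other_peaks(self, rng):
        regions = RegionSet(
            [iv("chrA", int(s), int(s) + 200) for s in rng.integers(0, 9_800, 50)],
            width=200,
        )
        others = [
            iv("chrA", int(s), int(s) + 150) for s in rng.integers(0, 9_800, 30)
        ]
        kept_sizes = [
            len(exclude_overlapping(regions, others[:k]))
            for k in range(len(others) + 1)
        ]
        assert all(a >= b for a, b in zip(kept_sizes, kept_sizes[1:]))


class TestSampleBaseline:
    def test_count_width_and_determinism(self):
        a = sample_baseline(SIZES, n=500, width=200, seed=42)
        b = sample_baseline(SIZES, n=500, width=200, seed=42)
        assert len(a) == 500 and all(len(r) == 200 for r in a)
        assert [(r.chrom, r.start) for r in a] == [(r.chrom, r.start) for r in b]
        c = sample_baseline(SIZES, n=500, width=200, seed=43)
        assert [(r.chrom, r.start) for r in a] != [(r.chrom, r.start) for r in c]

    def test_never_crosses_chromosome_end(self):
        out = sample_baseline({"chrA": 250}, n=200, width=200, seed=1)
        assert all(r.start >= 0 and r.end <= 250 for r in out)

    def test_all_chroms_too_short_fails(self):
        with pytest.raises(ValueError, match="at least"):
            sample_baseline({"chrA": 100}, n=5, width=200, seed=1)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            sample_baseline(SIZES, n=5, width=200)

    def test_n_rich_draws_rejected(self):
        genome = {"chrN": "N" * 5_000, "chrC": "ACGT" * 2_500}
        sizes = {c: len(s) for c, s in genome.items()}
        out = sample_baseline(
            sizes, n=50, width=200, seed=5, genome=genome, max_n_fraction=0.1
        )
        assert all(r.chrom == "chrC" for r in out)

    def test_unplaceable_fails_with_diagnostic(self):
        genome = {"chrN": "N" * 5_000}
        with pytest.raises(RuntimeError, match="could not place"):
            sample_baseline(
                {"chrN": 5_000}, n=10, width=200, seed=5,
                genome=genome, max_n_fraction=0.1,
            )

    def test_uniform_over_two_chromosome_toy_genome(self):
        """Empirical start distribution is uniform (chi-square, p > 0.01)."""
        sizes = {"c1": 2_000, "c2": 1_000}
        out = sample_baseline(sizes, n=20_000, width=200, seed=11)
        # bin valid starts: c1 has 1801 valid starts, c2 has 801
        nbins = 20
        counts = []
        for chrom, L in sizes.items():
            valid = L - 200 + 1
            starts = np.array([r.start for r in out if r.chrom == chrom])
            edges = np.linspace(0, valid, nbins // 2 + 1)
            counts.extend(np.histogram(starts, bins=edges)[0])
        expected = np.repeat(
            [1801 / (1801 + 801) * 20_000 / (nbins // 2),
             801 / (1801 + 801) * 20_000 / (nbins // 2)],
            nbins // 2,
        )
        _, p = stats.chisquare(counts, expected * sum(counts) / sum(expected))
        assert p > 0.01


class TestExtractSequences:
    def test_exact_slice_uppercase(self):
        genome = {"chrA": "gcgccAAAA"}
        (pair,) = extract_sequences(genome, [iv("chrA", 0, 5)])
        assert pair[1] == "GCGCC"

    def test_round_trip_through_fasta(self, toy_genome, toy_genome_fasta):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(toy_genome_fasta))
        regions = [iv("chrA", 123, 323), iv("chrB", 0, 200), iv("chrB", 2_800, 3_000)]
        for r, seq in extract_sequences(fasta, regions):
            assert seq == toy_genome[r.chrom][r.start : r.end]

    def test_out_of_bounds_names_region(self):
        with pytest.raises(ValueError, match="chrA:100-9000"):
            extract_sequences({"chrA": "A" * 500}, [iv("chrA", 100, 9_000)])

    def test_missing_chrom_names_region(self):
        with pytest.raises(KeyError, match="chrZ"):
            extract_sequences({"chrA": "A" * 500}, [iv("chrZ", 0, 10)])


class TestIO:
    def test_bed_and_narrowpeak_round_trip(self, tmp_path):
        regions = [
            iv("chr1", 10, 210, strand="+", name="p1", summit_offset=55),
            iv("chr2", 0, 500, name="p2"),
        ]
        bed = tmp_path / "x.bed"
        npk = tmp_path / "x.narrowPeak"
        write_bed(regions, bed)
        write_narrowpeak(regions, npk)
        back = read_bed(bed)
        assert [(r.chrom, r.start, r.end, r.name) for r in back] == [
            ("chr1", 10, 210, "p1"), ("chr2", 0, 500, "p2"),
        ]
        back_np = read_bed(npk)
        assert back_np[0].summit_offset == 55
        assert back_np[1].summit_offset == -1

    def test_bed3_minimal(self, tmp_path):
        p = tmp_path / "min.bed"
        p.write_text("chr1\t5\t105\n#comment\n")
        (r,) = read_bed(p)
        assert (r.start, r.end, r.strand) == (5, 105, ".")

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        assert read_chrom_sizes(p) == {"chr1": 1000, "chr2": 500}

    def test_tss_bed6(self, tmp_path):
        p = tmp_path / "tss.bed"
        p.write_text("chr1\t100\t101\tg1\t0\t+\nchr1\t200\t300\tg2\t0\t-\n")
        tss = read_tss(p)
        assert (tss[0].position, tss[0].strand) == (100, "+")
        # minus-strand record: TSS is the 3' BED coordinate (end - 1)
        assert (tss[1].position, tss[1].strand) == (299, "-")

    def test_tss_gff3_transcripts(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t500\t.\t+\t.\tID=gene1\n"
            "chr1\tsrc\ttranscript\t101\t500\t.\t+\t.\tID=tx1;Parent=gene1\n"
            "chr1\tsrc\ttranscript\t701\t900\t.\t-\t.\tID=tx2\n"
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=tx1\n"
        )
        tss = read_tss(p)
        assert len(tss) == 2
        # + transcript: TSS at GFF start (1-based 101 -> 0-based 100)
        assert (tss[0].position, tss[0].strand, tss[0].gene_id) == (100, "+", "tx1")
        # - transcript: TSS at GFF end (1-based 900 -> 0-based 899)
        assert (tss[1].position, tss[1].strand) == (899, "-")
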