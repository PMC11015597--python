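"""Interval arithmetic, coordinate conventions, and flat-file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromstate.genome import (
    BedParseError,
    GeneModel,
    GenomicInterval,
    SignalTrack,
    StateSegmentation,
    coverage_by_set,
    merge_intervals,
    overlap_fraction,
    read_bed,
    read_genes,
    write_bed,
)


class TestGenomicInterval:
    def test_length_and_validation(self):
        iv = GenomicInterval("chr1", 0, 100)
        assert iv.length == 100
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, strand="x")


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "a,b,denom,expected",
        [
            (("chr1", 0, 100), ("chr1", 50, 150), "b", 0.5),
            (("chr1", 0, 100), ("chr1", 0, 100), "a", 1.0),
            (("chr1", 0, 10), ("chr2", 0, 10), "b", 0.0),
            (("chr1", 0, 100), ("chr1", 50, 150), "a", 0.5),
        ],
    )
    def test_examples(self, a, b, denom, expected):
        assert overlap_fraction(GenomicInterval(*a), GenomicInterval(*b), denom) == expected

    @given(
        s1=st.integers(0, 500), l1=st.integers(1, 200),
        s2=st.integers(0, 500), l2=st.integers(1, 200),
    )
    @settings(max_examples=100, derandomize=True)
    def test_numerator_symmetric_in_intersection(self, s1, l1, s2, l2):
        """The shared-base count is the same whichever denominator is used."""
        a = GenomicInterval("c", s1, s1 + l1)
        b = GenomicInterval("c", s2, s2 + l2)
        assert overlap_fraction(a, b, "a") * a.length == pytest.approx(
            overlap_fraction(a, b, "b") * b.length
        )


class TestCoverageBySet:
    def test_disjoint_union(self):
        t = GenomicInterval("chr1", 0, 100)
        regs = [GenomicInterval("chr1", 0, 30), GenomicInterval("chr1", 60, 90)]
        assert coverage_by_set(t, regs) == 0.6

    def test_overlapping_union_saturates(self):
        t = GenomicInterval("chr1", 0, 100)
        regs = [GenomicInterval("chr1", 0, 60), GenomicInterval("chr1", 40, 100)]
        assert coverage_by_set(t, regs) == 1.0

    def test_other_chromosome(self):
        t = GenomicInterval("chr1", 0, 100)
        assert coverage_by_set(t, [GenomicInterval("chr2", 0, 100)]) == 0.0

    def test_matches_per_base_oracle(self, rng):
        """Interval coverage equals brute-force per-base counting."""
        for _ in range(30):
            t0 = int(rng.integers(0, 5_000))
            target = GenomicInterval("c", t0, t0 + int(rng.integers(100, 5_000)))
            regs = []
            for _ in range(int(rng.integers(0, 15))):
                s = int(rng.integers(0, 9_000))
                regs.append(GenomicInterval("c", s, s + int(rng.integers(1, 1_500))))
            base = np.zeros(12_000, dtype=bool)
            for r in regs:
                base[r.start : r.end] = True
            expected = base[target.start : target.end].mean()
            assert coverage_by_set(target, regs) == pytest.approx(expected)


class TestBedIO:
    def test_parse_merge_roundtrip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\t50\t150\nchr2\t10\t20\n")
        raw = read_bed(p)
        assert raw[0] == GenomicInterval("chr1", 0, 100)
        merged = read_bed(p, merge_overlaps=True)
        assert merged == [GenomicInterval("chr1", 0, 150), GenomicInterval("chr2", 10, 20)]
        out = tmp_path / "b.bed"
        write_bed(raw, out)
        assert read_bed(out) == raw  # coordinate round trip is exact

    def test_empty_interval_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\t100\t100\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_malformed_line_named(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\tten\t100\n")
        with pytest.raises(BedParseError, match=":1"):
            read_bed(p)

    def test_gzip_transparent(self, tmp_path):
        import gzip

        p = tmp_path / "a.bed.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t5\t50\n")
        assert read_bed(p) == [GenomicInterval("chr1", 5, 50)]


class TestReadGenes:
    def _write_gff(self, tmp_path, strand):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            f"chr1\tsrc\tgene\t1\t100\t.\t{strand}\t.\tID=g1\n"
        )
        return p

    def test_gff3_plus_strand_coordinates(self, tmp_path):
        g = read_genes(self._write_gff(tmp_path, "+"))[0]
        assert (g.body.start, g.body.end) == (0, 100)
        assert g.tss == 0 and g.tts == 99

    def test_gff3_minus_strand_tss(self, tmp_path):
        g = read_genes(self._write_gff(tmp_path, "-"))[0]
        assert g.tss == 99 and g.tts == 0

    def test_gff3_missing_strand_errors(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\tgene\t1\t100\t.\t.\t.\tID=g1\n")
        with pytest.raises(ValueError, match="strand"):
            read_genes(p)

    def test_bed12_block_gap_becomes_intron(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t100\tg1\t0\t+\t0\t100\t0\t2\t30,30\t0,70\n")
        g = read_genes(p, format="bed12")[0]
        assert g.introns == [GenomicInterval("chr1", 30, 70)]
        assert len(g.coding_exons) == 2

    def test_child_outside_parent_errors(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t11\t100\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tCDS\t1\t50\t.\t+\t.\tID=c1;Parent=g1\n"
        )
        with pytest.raises(ValueError, match="outside"):
            read_genes(p)


class TestGeneModelInvariants:
    def test_subfeature_outside_body_rejected(self):
        body = GenomicInterval("chr1", 10, 100, "+")
        with pytest.raises(ValueError, match="outside body"):
            GeneModel("g", body, "+", coding_exons=[GenomicInterval("chr1", 0, 50)])

    def test_synthetic_genes_obey_structure(self, small_genome):
        """Simulated genes: subfeatures tile the body, introns are the gaps."""
        genes, _, _ = small_genome
        for g in genes:
            blocks = g.exonic_blocks()
            covered = sum(b.length for b in blocks) + sum(i.length for i in g.introns)
            assert covered == g.body.length
            for left, right in zip(blocks, blocks[1:]):
                assert any(i.start == left.end and i.end == right.start for i in g.introns)


class TestStateSegmentation:
    def test_totals_sum_to_bin_count(self, small_genome):
        _, seg, _ = small_genome
        assert seg.state_totals().sum() == len(seg)

    def test_bed_roundtrip(self, small_genome, tmp_path):
        _, seg, _ = small_genome
        p = tmp_path / "states.bed"
        seg.to_bed(p)
        seg2 = StateSegmentation.from_bed(p, seg.n_states)
        assert len(seg2) == len(seg)
        assert np.array_equal(seg2.state_totals(), seg.state_totals())

    def test_overlapping_bins_rejected(self):
        bins = [
            (GenomicInterval("chr1", 0, 100), 1),
            (GenomicInterval("chr1", 50, 150), 2),
        ]
        with pytest.raises(ValueError, match="overlap"):
            StateSegmentation(bins, 2)


class TestSignalTrack:
    def test_uncovered_reads_zero(self):
        t = SignalTrack({"c": (np.array([100]), np.array([200]), np.array([3.0]))})
        assert t.mean("c", 0, 100) == 0.0
        assert t.mean("c", 100, 200) == 3.0
        assert t.mean("c", 0, 200) == 1.5

    def test_integral_matches_per_base(self, rng):
        starts = np.array([0, 120, 400])
        ends = np.array([100, 300, 450])
        vals = np.array([2.0, 0.5, 4.0])
        t = SignalTrack({"c": (starts, ends, vals)})
        base = np.zeros(600)
        for s, e, v in zip(starts, ends, vals):
            base[s:e] = v
        for _ in range(50):
            a = int(rng.integers(0, 590))
            b = a + int(rng.integers(1, 600 - a))
            assert t.mean("c", a, b) == pytest.approx(base[a:b].mean())

    def test_bedgraph_roundtrip(self, tmp_path):
        t = SignalTrack({"c": (np.array([0, 50]), np.array([50, 80]), np.array([1.5, 0.25]))})
        p = tmp_path / "t.bedGraph"
        t.to_bedgraph(p)
        t2 = SignalTrack.from_bedgraph(p)
        assert t2.mean("c", 0, 80) == pytest.approx(t.mean("c", 0, 80))

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            SignalTrack({"c": (np.array([0]), np.array([10]), np.array([-1.0]))})


class TestMergeIntervals:
    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 60)), min_size=0, max_size=20
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_merge_is_disjoint_and_preserves_bases(self, raw):
        """Merged output is sorted, disjoint, and covers the same bases."""
        ivs = [GenomicInterval("c", s, s + l) for s, l in raw]
        merged = merge_intervals(ivs)
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start  # book-ended runs are unioned too
        base = np.zeros(400, dtype=bool)
        for iv in ivs:
            base[iv.start : iv.end] = True
        assert sum(m.length for m in merged) == int(base.sum())
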