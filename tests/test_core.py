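"""Coordinate model, format round-trips and interval algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tewave import (FormatError, GenomeLayout, GenomicInterval, GeneRecord,
                    SignalTrack, extend_clip, five_prime_point,
                    intersect_fraction, merge_intervals, read_annotation,
                    read_bed, read_bedgraph, read_chrom_sizes,
                    read_gtf_genes, read_narrowpeak, read_repeatmasker,
                    shuffle_intervals, write_bed, write_bedgraph,
                    write_gtf_genes, write_repeatmasker)
from tewave.core import TERecord


def brute_overlaps(a, b):
    """Independent O(n*m) oracle for interval overlap pairs."""
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            ov = min(x.end, y.end) - max(x.start, y.start)
            if ov > 0:
                out.append((i, j, ov))
    return sorted(out)


class TestInterval:
    def test_rejects_degenerate_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 10, "x")

    def test_layout_bounds_check(self, small_layout):
        small_layout.check(GenomicInterval("chr1", 0, 100_000))
        with pytest.raises(ValueError):
            small_layout.check(GenomicInterval("chr1", 0, 100_001))
        with pytest.raises(ValueError):
            small_layout.check(GenomicInterval("chrX", 0, 10))


class TestReaders:
    def test_bed_native_half_open(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\tx\t0\t+\n")
        (iv,) = read_bed(p)
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr1", 100, 200, "+")

    def test_bed_round_trip(self, tmp_path):
        ivs = [GenomicInterval("chr1", 5, 50, "+", "a"),
               GenomicInterval("chr2", 0, 7, "-", "b"),
               GenomicInterval("chr1", 99, 100, ".", None)]
        p = tmp_path / "rt.bed"
        write_bed(p, ivs)
        assert read_bed(p) == ivs

    def test_bed_malformed_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\tfoo\t300\n")
        with pytest.raises(FormatError, match="bad.bed:2"):
            read_bed(p)
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(FormatError, match="end <= start"):
            read_bed(p)

    def test_gtf_one_based_conversion(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text('chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n')
        (g,) = read_gtf_genes(p)
        assert (g.span.start, g.span.end) == (100, 200)

    def test_gtf_round_trip_with_substructure(self, tmp_path, annotation):
        genes = annotation.genes[:40]
        p = tmp_path / "rt.gtf"
        write_gtf_genes(p, genes)
        back = read_gtf_genes(p)
        assert [g.span for g in back] == [g.span for g in genes]
        assert [g.exons for g in back] == [g.exons for g in genes]
        assert [g.category for g in back] == [g.category for g in genes]

    def test_repeatmasker_consensus_span(self, tmp_path):
        p = tmp_path / "rm.tsv"
        p.write_text(
            "genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\t"
            "repFamily\trepStart\trepEnd\nchr1\t3037726\t3043047\t+\t"
            "L1Md_A\tLINE\tL1\t279\t5586\n")
        (te,) = read_repeatmasker(p)
        assert (te.consensus_start, te.consensus_end) == (279, 5586)
        assert te.locus.start == 3037726

    def test_repeatmasker_round_trip(self, tmp_path, annotation):
        p = tmp_path / "rt.tsv"
        write_repeatmasker(p, annotation.tes[:100])
        back = read_repeatmasker(p)
        assert [t.locus for t in back] == \
            [t.locus for t in annotation.tes[:100]]
        assert [t.consensus_end for t in back] == \
            [t.consensus_end for t in annotation.tes[:100]]

    def test_bedgraph_round_trip(self, tmp_path):
        track = SignalTrack([(GenomicInterval("chr1", 0, 10), 2.0),
                             (GenomicInterval("chr1", 20, 25), 0.5)])
        p = tmp_path / "t.bedGraph"
        write_bedgraph(p, track)
        assert read_bedgraph(p).steps() == track.steps()

    def test_unknown_chromosomes_dropped(self, tmp_path, small_layout):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t10\nchrUn_scaffold\t0\t10\n")
        assert len(read_bed(p, small_layout)) == 1

    def test_dispatch_and_chrom_sizes(self, tmp_path):
        p = tmp_path / "c.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        layout = read_annotation(p, "chrom-sizes")
        assert layout.length("chr2") == 500
        with pytest.raises(ValueError):
            read_annotation(p, "not-a-format")

    def test_narrowpeak_reader(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t10\t50\tpk1\t0\t.\t8.5\t-1\t-1\t-1\n")
        ((iv, score),) = read_narrowpeak(p)
        assert iv.length == 40 and score == 8.5


class TestIntersectFraction:
    def test_boundary_exactly_met(self):
        a = [GenomicInterval("c", 10, 20)]
        b = [GenomicInterval("c", 15, 30)]
        (rec,) = intersect_fraction(a, b, 0.5)
        assert rec.overlap_bp == 5 and rec.frac_a == 0.5

    def test_below_fraction_not_reported(self):
        a = [GenomicInterval("c", 10, 20)]
        b = [GenomicInterval("c", 19, 30)]
        assert intersect_fraction(a, b, 0.5) == []
        assert len(intersect_fraction(a, b, 0.0)) == 1

    def test_multiple_overlaps_enumerated(self):
        a = [GenomicInterval("c", 0, 100)]
        b = [GenomicInterval("c", 0, 60), GenomicInterval("c", 40, 100)]
        recs = intersect_fraction(a, b, 0.0)
        assert sorted(r.overlap_bp for r in recs) == [60, 60]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_and_monotone(self, data):
        def ivs(n):
            out = []
            for _ in range(n):
                s = data.draw(st.integers(0, 80))
                e = data.draw(st.integers(s + 1, 100))
                chrom = data.draw(st.sampled_from(["c1", "c2"]))
                out.append(GenomicInterval(chrom, s, e))
            return out
        a, b = ivs(data.draw(st.integers(0, 12))), ivs(data.draw(st.integers(0, 12)))
        got = sorted((r.a_index, r.b_index, r.overlap_bp)
                     for r in intersect_fraction(a, b, 0.0))
        assert got == brute_overlaps(a, b)
        # symmetry of overlap_bp and monotonicity in min_frac
        rev = {(r.b_index, r.a_index): r.overlap_bp
               for r in intersect_fraction(b, a, 0.0)}
        for i, j, ov in got:
            assert rev[(i, j)] == ov
        hi = {(r.a_index, r.b_index)
              for r in intersect_fraction(a, b, 0.7)}
        assert hi <= {(i, j) for i, j, _ in got}


class TestExtendClip:
    def test_clips_both_ends(self):
        layout = GenomeLayout.from_dict({"c": 120})
        iv = extend_clip(GenomicInterval("c", 50, 60), 100, 100, layout)
        assert (iv.start, iv.end) == (0, 120)

    def test_tss_window(self):
        layout = GenomeLayout.from_dict({"c": 10_000})
        iv = extend_clip(GenomicInterval("c", 500, 501, "+"), 100, 100, layout)
        assert (iv.start, iv.end, iv.strand) == (400, 601, "+")

    def test_asymmetric(self):
        layout = GenomeLayout.from_dict({"c": 1000})
        iv = extend_clip(GenomicInterval("c", 0, 10), 5, 5, layout)
        assert (iv.start, iv.end) == (0, 15)


class TestFivePrimePoint:
    @pytest.mark.parametrize("strand,expected", [("+", (100, 101)),
                                                 ("-", (899, 900))])
    def test_strand_aware(self, strand, expected):
        g = GeneRecord("g", GenomicInterval("c", 100, 900, strand))
        tss = five_prime_point(g)
        assert (tss.start, tss.end) == expected

    def test_single_bp_gene_is_identity(self):
        for strand in "+-":
            g = GenomicInterval("c", 7, 8, strand)
            assert (five_prime_point(g).start, five_prime_point(g).end) == (7, 8)

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError):
            five_prime_point(GenomicInterval("c", 0, 10))


class TestShuffle:
    def test_preserves_lengths_and_determinism(self, small_layout):
        ivs = [GenomicInterval("chr1", 0, 5), GenomicInterval("chr1", 10, 20),
               GenomicInterval("chr2", 0, 20)]
        s1 = shuffle_intervals(ivs, small_layout, 11)
        s2 = shuffle_intervals(ivs, small_layout, 11)
        assert s1 == s2
        assert sorted(x.length for x in s1) == [5, 10, 20]

    def test_same_chromosome_mode(self, small_layout):
        ivs = [GenomicInterval("chr2", 0, 100)] * 20
        out = shuffle_intervals(ivs, small_layout, 1, mode="same-chromosome")
        assert all(x.chrom == "chr2" for x in out)

    def test_too_long_interval_raises(self):
        layout = GenomeLayout.from_dict({"c": 100})
        with pytest.raises(ValueError):
            shuffle_intervals([GenomicInterval("c", 0, 99),
                               GenomicInterval("other", 0, 101)], layout, 0)

    def test_mean_overlap_matches_closed_form(self):
        # one 1-kb interval shuffled on a 1-Mb chromosome vs a fixed
        # 10-kb feature: E[overlap] has a closed form under uniform
        # placement of the start in [0, G-L].
        G, L, F = 1_000_000, 1_000, 10_000
        layout = GenomeLayout.from_dict({"c": G})
        feature = GenomicInterval("c", 500_000, 500_000 + F)
        n = 10_000
        rng = np.random.default_rng(0)
        draws = shuffle_intervals([GenomicInterval("c", 0, L)] * n, layout,
                                  rng)
        mean = np.mean([feature.overlap_bp(iv) for iv in draws])
        # exact expectation by summing overlap over all start positions
        starts = np.arange(G - L + 1)
        ov = np.clip(np.minimum(starts + L, feature.end)
                     - np.maximum(starts, feature.start), 0, None)
        expected = ov.mean()
        sd = np.std([feature.overlap_bp(iv) for iv in draws]) / np.sqrt(n)
        assert abs(mean - expected) < 5 * sd

    def test_per_base_placement_uniform(self):
        layout = GenomeLayout.from_dict({"a": 1000, "b": 1000})
        n = 2000
        rng = np.random.default_rng(3)
        draws = shuffle_intervals([GenomicInterval("a", 0, 10)] * n, layout,
                                  rng)
        cover = {"a": np.zeros(1000), "b": np.zeros(1000)}
        for iv in draws:
            cover[iv.chrom][iv.start:iv.end] += 1
        freq = np.concatenate([cover["a"], cover["b"]]) / n
        p = 10 / (2 * (1000 - 10 + 1))  # per-base coverage probability
        se = np.sqrt(p * (1 - p) / n)
        # interior bases (edges have reduced coverage by construction)
        interior = np.concatenate([cover["a"][10:-10], cover["b"][10:-10]]) / n
        assert np.all(np.abs(interior - p) < 5 * se)


class TestSignalTrack:
    def test_range_sum_and_mean(self):
        track = SignalTrack([(GenomicInterval("c", 0, 100), 2.0),
                             (GenomicInterval("c", 100, 200), 3.0)])
        assert track.range_sum(GenomicInterval("c", 0, 200)) == 500
        assert track.range_sum(GenomicInterval("c", 50, 150)) == 250
        means = track.range_mean("c", np.array([0, 100, 200, 300]))
        assert list(means) == [2.0, 3.0, 0.0]

    def test_uncovered_is_zero(self):
        track = SignalTrack([(GenomicInterval("c", 100, 200), 5.0)])
        assert track.range_sum(GenomicInterval("c", 0, 50)) == 0.0

    def test_rejects_overlapping_steps(self):
        with pytest.raises(ValueError):
            SignalTrack([(GenomicInterval("c", 0, 10), 1.0),
                         (GenomicInterval("c", 5, 15), 1.0)])


def test_merge_intervals_unions_overlaps():
    ivs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 20),
           GenomicInterval("c", 30, 40), GenomicInterval("d", 0, 1)]
    merged = merge_intervals(ivs)
    assert [(m.chrom, m.start, m.end) for m in merged] == \
        [("c", 0, 20), ("c", 30, 40), ("d", 0, 1)]
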