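"""Peak filtering, priority annotation, TE assignment, AUC, membership."""

import numpy as np
import pytest

from tewave import (GenomeLayout, GenomicInterval, GeneRecord, GeneModel,
                    PeakRecord, SignalTrack, annotate_peak_categories,
                    assign_peaks_to_te, filter_by_auc,
                    filter_peaks_min_length, peak_auc, stage_membership,
                    feature_peak_enrichment)
from tewave.core import TERecord


def peak(start, end, stage="s", chrom="c"):
    return PeakRecord(GenomicInterval(chrom, start, end), stage)


@pytest.fixture()
def layout():
    return GenomeLayout.from_dict({"c": 200_000})


@pytest.fixture()
def gene_model(layout):
    # + strand gene at [50,000, 60,000) with exons/UTRs, second gene on -
    g1 = GeneRecord(
        "g1", GenomicInterval("c", 50_000, 60_000, "+"),
        exons=(GenomicInterval("c", 50_000, 50_500, "+"),
               GenomicInterval("c", 59_000, 60_000, "+")),
        five_utrs=(GenomicInterval("c", 50_000, 50_100, "+"),),
        three_utrs=(GenomicInterval("c", 59_900, 60_000, "+"),))
    g2 = GeneRecord("g2", GenomicInterval("c", 100_000, 110_000, "-"))
    return GeneModel.build([g1, g2], layout)


class TestLengthFilter:
    def test_strictly_longer_than_ten(self):
        kept = filter_peaks_min_length([peak(0, 10), peak(0, 11)])
        assert [p.locus.length for p in kept] == [11]

    def test_empty_input(self):
        assert filter_peaks_min_length([]) == []


class TestPriorityAnnotation:
    def test_promoter_within_3kb_upstream(self, gene_model):
        (p,) = annotate_peak_categories([peak(48_500, 48_700)], gene_model)
        assert p.category == "promoter"

    def test_promoter_beats_exon_of_other_gene(self, layout):
        # peak overlaps g1's promoter window and g2's exon: promoter wins
        g1 = GeneRecord("g1", GenomicInterval("c", 10_000, 20_000, "+"))
        g2 = GeneRecord("g2", GenomicInterval("c", 5_000, 8_500, "+"),
                        exons=(GenomicInterval("c", 5_000, 8_500, "+"),))
        model = GeneModel.build([g1, g2], layout)
        (p,) = annotate_peak_categories([peak(8_000, 8_400)], model)
        assert p.category == "promoter"

    def test_intron_and_exon_resolution(self, gene_model):
        (p,) = annotate_peak_categories([peak(55_000, 55_200)], gene_model)
        assert p.category == "intron"
        (p,) = annotate_peak_categories([peak(59_200, 59_300)], gene_model)
        assert p.category == "exon"

    def test_utrs_outrank_exons(self, gene_model):
        # 3'UTR sits inside the terminal exon: UTR has priority
        (p,) = annotate_peak_categories([peak(59_950, 59_990)], gene_model)
        assert p.category == "3UTR"

    def test_downstream_window(self, gene_model):
        # g1 ends at 60,000 (+): within 3 kb past the end, but note the
        # promoter window of nothing else reaches here
        (p,) = annotate_peak_categories([peak(62_000, 62_100)], gene_model)
        assert p.category == "downstream"
        # for the - strand gene, downstream is left of its start
        (p,) = annotate_peak_categories([peak(97_500, 97_600)], gene_model)
        assert p.category in ("downstream", "promoter")

    def test_far_from_everything_is_intergenic(self, gene_model):
        (p,) = annotate_peak_categories([peak(150_000, 150_500)], gene_model)
        assert p.category == "intergenic"

    def test_every_peak_gets_exactly_one_category(self, gene_model):
        rng = np.random.default_rng(0)
        peaks = [peak(int(s), int(s) + 200)
                 for s in rng.integers(0, 190_000, size=300)]
        out = annotate_peak_categories(peaks, gene_model)
        assert all(p.category is not None for p in out)


class TestTeAssignment:
    def te(self, start, end, name, subfam="L1Md_A"):
        return TERecord(GenomicInterval("c", start, end, "+", name),
                        subfamily=subfam, te_class="LINE", family="L1",
                        consensus_start=1, consensus_end=end - start)

    def test_longest_intersection_wins(self):
        p = peak(100, 200)
        tes = [self.te(40, 160, "short"), self.te(120, 300, "long")]
        (got,) = assign_peaks_to_te([p], tes)
        assert got.te_id == "long"  # overlaps 80 vs 60

    def test_half_overlap_boundary(self):
        p = peak(100, 200)
        (unassigned,) = assign_peaks_to_te([p], [self.te(151, 260, "x")])
        assert unassigned.te_id is None  # 49/100 < 0.5
        (assigned,) = assign_peaks_to_te([p], [self.te(150, 260, "x")])
        assert assigned.te_id == "x"  # exactly 0.5

    def test_peak_inside_te(self):
        (got,) = assign_peaks_to_te([peak(100, 200)],
                                    [self.te(0, 1000, "big")])
        assert got.te_id == "big"

    def test_tie_breaks_on_smaller_te_start(self):
        p = peak(100, 200)
        tes = [self.te(120, 220, "right"), self.te(80, 180, "left")]
        (got,) = assign_peaks_to_te([p], tes)  # both overlap 80
        assert got.te_id == "left"

    def test_at_most_one_te_per_peak(self, annotation, stage_peaks):
        from tewave import join_line1_fragments
        joined, _ = join_line1_fragments(
            [t for t in annotation.tes if t.te_class == "LINE"])
        tes = joined + [t for t in annotation.tes if t.te_class != "LINE"]
        peaks = [PeakRecord(p.locus, p.stage)
                 for p in stage_peaks.atac["early2C"]]
        out = assign_peaks_to_te(peaks, tes)
        assert len(out) == len(peaks)
        assert all(isinstance(p.te_id, (str, type(None))) for p in out)

    def test_rejects_genic_peaks(self):
        p = PeakRecord(GenomicInterval("c", 0, 100), "s", category="exon")
        with pytest.raises(ValueError):
            assign_peaks_to_te([p], [])


class TestAuc:
    def test_strict_threshold_500(self):
        track = SignalTrack([(GenomicInterval("c", 0, 100), 2.0),
                             (GenomicInterval("c", 100, 200), 3.0)])
        p = peak(0, 200)
        assert peak_auc(p, track) == 500.0
        assert filter_by_auc([p], track) == []  # 500 is not > 500

    def test_above_threshold_kept_with_auc(self):
        track = SignalTrack([(GenomicInterval("c", 0, 100), 2.0),
                             (GenomicInterval("c", 100, 201), 3.0)])
        (kept,) = filter_by_auc([peak(0, 201)], track)
        assert kept.auc == 503.0

    def test_zero_signal_removed(self):
        assert filter_by_auc([peak(0, 100)], SignalTrack()) == []

    def test_additive_over_partition(self):
        rng = np.random.default_rng(1)
        steps = []
        pos = 0
        for _ in range(20):
            w = int(rng.integers(5, 50))
            steps.append((GenomicInterval("c", pos, pos + w),
                          float(rng.uniform(0, 4))))
            pos += w + int(rng.integers(0, 10))
        track = SignalTrack(steps)
        whole = peak_auc(peak(0, pos), track)
        parts = sum(peak_auc(peak(a, a + 100), track)
                    for a in range(0, pos, 100) if a + 100 <= pos)
        tail = peak_auc(peak(pos - pos % 100, pos), track) \
            if pos % 100 else 0.0
        assert whole == pytest.approx(parts + tail)


class TestStageMembership:
    def feats(self, names):
        return [GenomicInterval("c", 1000 * i, 1000 * i + 100, ".", n)
                for i, n in enumerate(names)]

    def sets_for(self, members):
        feats = {f.name: f for f in self.feats(["m1", "m2", "m3", "m4"])}
        return {stage: [PeakRecord(feats[m], stage) for m in ms]
                for stage, ms in members.items()}

    def test_earlier_fraction_set_arithmetic(self):
        feats = self.feats(["m1", "m2", "m3", "m4"])
        sets = self.sets_for({"early": ["m1", "m2"], "late": ["m2", "m3"],
                              "eight": ["m1", "m2", "m3", "m4"]})
        table, counts, frac = stage_membership(
            feats, sets, late_stage="eight", early_stages=("early", "late"))
        assert frac == pytest.approx(3 / 4)
        assert table.loc["m4"].tolist() == [False, False, True]

    def test_single_stage_membership_vector(self):
        feats = self.feats(["m1", "m2"])
        sets = self.sets_for({"only": ["m2"]})
        table, counts, _ = stage_membership(feats, sets)
        assert table["only"].tolist() == [False, True]
        assert counts[()] == 1 and counts[("only",)] == 1

    def test_disjoint_stages_fraction_zero(self):
        feats = self.feats(["m1", "m2"])
        sets = self.sets_for({"a": ["m1"], "b": ["m2"]})
        _, _, frac = stage_membership(feats, sets, late_stage="b",
                                      early_stages=("a",))
        assert frac == 0.0

    def test_unknown_stage_label_rejected(self):
        feats = self.feats(["m1"])
        with pytest.raises(ValueError):
            stage_membership(feats, self.sets_for({"a": ["m1"]}),
                             late_stage="z")


class TestFeaturePeakEnrichment:
    def test_planted_features_enriched(self, layout):
        rng = np.random.default_rng(8)
        feats = [GenomicInterval("c", int(s), int(s) + 200, "+", f"f{i}")
                 for i, s in enumerate(rng.integers(0, 190_000, 30))]
        on_feats = [PeakRecord(GenomicInterval("c", f.start, f.end), "s")
                    for f in feats[:25]]
        res = feature_peak_enrichment(feats, {"s": on_feats}, layout,
                                      n_perm=100, seed=0)["s"]
        assert res.observed == 25
        assert res.z > 3

    def test_endpoint_variant_uses_end_coordinate(self, layout):
        feats = [GenomicInterval("c", 1000, 2000, "+", "f")]
        at_end = [PeakRecord(GenomicInterval("c", 1950, 2100), "s")]
        at_start = [PeakRecord(GenomicInterval("c", 900, 1100), "s")]
        r_end = feature_peak_enrichment(feats, {"s": at_end}, layout,
                                        endpoint=True, n_perm=10, seed=0)
        r_start = feature_peak_enrichment(feats, {"s": at_start}, layout,
                                          endpoint=True, n_perm=10, seed=0)
        assert r_end["s"].observed == 1
        assert r_start["s"].observed == 0
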