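"""ATAC/Pol-II peak filtering, genic annotation and TE assignment.

Peaks are annotated against a union gene model with the ChIPseeker
priority order (promoter > 5'UTR > 3'UTR > exon > intron > downstream >
intergenic); intergenic peaks can then be assigned to at most one TE by
the bedtools ``-f 0.5 -wao`` + longest-intersection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (GenomeLayout, GenomicInterval, GeneRecord, SignalTrack,
                   TERecord, extend_clip, five_prime_point,
                   intersect_fraction, overlaps_any, shuffle_intervals)
from .stats import EnrichmentResult, attach_fdr, summarize_null

CATEGORIES = ("promoter", "5UTR", "3UTR", "exon", "intron",
              "downstream", "intergenic")


@dataclass
class PeakRecord:
    """A called peak with stage label and computed attributes."""

    locus: GenomicInterval
    stage: str
    score: float | None = None
    auc: float | None = None
    category: str | None = None
    te_id: str | None = None
    te_subfamily: str | None = None

    def __post_init__(self):
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def filter_peaks_min_length(peaks: Sequence[PeakRecord],
                            min_exclusive: int = 10) -> list[PeakRecord]:
    """Keep peaks strictly longer than ``min_exclusive`` bp."""
    return [p for p in peaks if p.locus.length > min_exclusive]


@dataclass
class GeneModel:
    """Union gene model: the feature sets the priority annotation needs."""

    promoters: list[GenomicInterval]
    five_utrs: list[GenomicInterval]
    three_utrs: list[GenomicInterval]
    exons: list[GenomicInterval]
    spans: list[GenomicInterval]
    downstreams: list[GenomicInterval]

    @classmethod
    def build(cls, genes: Sequence[GeneRecord], layout: GenomeLayout,
              promoter_flank: int = 3000, downstream_window: int = 3000
              ) -> "GeneModel":
        promoters, downstreams = [], []
        for g in genes:
            tss = five_prime_point(g)
            promoters.append(
                extend_clip(tss, promoter_flank, promoter_flank, layout))
            span = g.span
            # window 3'-ward of the gene end
            if span.strand == "-":
                ds_start, ds_end = span.start - downstream_window, span.start
            else:
                ds_start, ds_end = span.end, span.end + downstream_window
            ds_start = max(0, ds_start)
            ds_end = min(layout.length(span.chrom), ds_end)
            if ds_end > ds_start:
                downstreams.append(
                    GenomicInterval(span.chrom, ds_start, ds_end, span.strand))
        return cls(
            promoters=promoters,
            five_utrs=[iv for g in genes for iv in g.five_utrs],
            three_utrs=[iv for g in genes for iv in g.three_utrs],
            exons=[iv for g in genes for iv in g.exons],
            spans=[g.span for g in genes],
            downstreams=downstreams,
        )


def annotate_peak_categories(peaks: Sequence[PeakRecord], model: GeneModel
                             ) -> list[PeakRecord]:
    """Assign every peak its single highest-priority genic category.

    A peak overlapping a gene span but none of that model's exon bases
    is intronic; peaks clear of all features are intergenic.
    """
    loci = [p.locus for p in peaks]
    feature_sets = (("promoter", model.promoters),
                    ("5UTR", model.five_utrs),
                    ("3UTR", model.three_utrs),
                    ("exon", model.exons),
                    ("intron", model.spans),
                    ("downstream", model.downstreams))
    category = np.array(["intergenic"] * len(peaks), dtype=object)
    unassigned = np.ones(len(peaks), dtype=bool)
    for label, features in feature_sets:
        if not features or not unassigned.any():
            continue
        hit = overlaps_any(loci, features)
        newly = hit & unassigned
        category[newly] = label
        unassigned &= ~hit
    return [replace(p, category=str(c)) for p, c in zip(peaks, category)]


def annotate_peak_category(peak: PeakRecord, model: GeneModel) -> str:
    """Single-peak convenience wrapper around the vectorised annotator."""
    return annotate_peak_categories([peak], model)[0].category


def assign_peaks_to_te(intergenic_peaks: Sequence[PeakRecord],
                       tes: Sequence[TERecord], min_frac: float = 0.5
                       ) -> list[PeakRecord]:
    """Assign each intergenic peak to at most one TE.

    A peak qualifies when >= ``min_frac`` of its bases overlap a TE;
    among qualifying TEs the longest intersection wins, ties broken by
    smaller TE genomic start.
    """
    for p in intergenic_peaks:
        if p.category not in (None, "intergenic"):
            raise ValueError("assign_peaks_to_te expects intergenic peaks")
    loci = [p.locus for p in intergenic_peaks]
    best: dict[int, tuple[int, int, TERecord]] = {}
    for rec in intersect_fraction(loci, tes, min_frac):
        te = tes[rec.b_index]
        key = (-rec.overlap_bp, te.locus.start)
        cur = best.get(rec.a_index)
        if cur is None or key < cur[:2]:
            best[rec.a_index] = (*key, te)
    out = []
    for i, p in enumerate(intergenic_peaks):
        if i in best:
            te = best[i][2]
            out.append(replace(p, te_id=te.te_id, te_subfamily=te.subfamily))
        else:
            out.append(replace(p, te_id=None, te_subfamily=None))
    return out


def peak_auc(peak: PeakRecord, signal: SignalTrack) -> float:
    """Area under the signal curve within the peak: sum(value x bp)."""
    return signal.range_sum(peak.locus)


def filter_by_auc(peaks: Sequence[PeakRecord], signal: SignalTrack,
                  min_exclusive: float = 500.0) -> list[PeakRecord]:
    """Keep peaks whose AUC strictly exceeds ``min_exclusive``."""
    out = []
    for p in peaks:
        auc = peak_auc(p, signal)
        if auc > min_exclusive:
            out.append(replace(p, auc=auc))
    return out


def stage_membership(features: Sequence[GenomicInterval],
                     peak_sets: dict[str, Sequence[PeakRecord]],
                     late_stage: str | None = None,
                     early_stages: Sequence[str] = ()
                     ) -> tuple[pd.DataFrame, pd.Series, float | None]:
    """Per-feature boolean peak overlap per stage, plus UpSet-style counts.

    Returns the membership table (features x stages), the count of
    features per membership pattern, and — when ``late_stage`` is given
    — the fraction of its positive features already positive in any of
    ``early_stages`` (the "bound already at an earlier stage" fraction).
    """
    if not peak_sets:
        raise ValueError("need at least one stage")
    for stage in (late_stage, *early_stages):
        if stage is not None and stage not in peak_sets:
            raise ValueError(f"unknown stage label {stage!r}")
    names = [f.name or str(i) for i, f in enumerate(features)]
    table = pd.DataFrame(index=names, dtype=bool)
    for stage, peaks in peak_sets.items():
        table[stage] = overlaps_any(features, [p.locus for p in peaks])
    patterns = table.apply(lambda row: tuple(row.index[row]), axis=1) \
        if len(table) else pd.Series(dtype=object)
    pattern_counts = patterns.value_counts()
    earlier_frac = None
    if late_stage is not None:
        late_pos = table[late_stage]
        if late_pos.any():
            earlier = table[list(early_stages)].any(axis=1) if early_stages \
                else pd.Series(False, index=table.index)
            earlier_frac = float(earlier[late_pos].mean())
        else:
            earlier_frac = 0.0
    return table, pattern_counts, earlier_frac


def feature_peak_enrichment(features: Sequence[GenomicInterval],
                            peak_sets: dict[str, Sequence[PeakRecord]],
                            layout: GenomeLayout, flank: int = 100,
                            endpoint: bool = False, n_perm: int = 1000,
                            seed: int = 0) -> dict[str, EnrichmentResult]:
    """Per-stage enrichment of peaks on flanked features vs shuffled peaks.

    Features (e.g. LINE-1 monomers) are extended by ``flank`` bp at both
    ends (or reduced to their end-point coordinate first, in the
    end-point variant); the statistic is the number of features
    overlapping at least one peak.  The null shuffles the peak
    coordinates genome-wide, 1,000 times by default.  FDR is corrected
    across stages.
    """
    if endpoint:
        feats = [replace(f, start=f.end - 1) for f in features]
    else:
        feats = list(features)
    windows = [extend_clip(f, flank, flank, layout) for f in feats]
    results: dict[str, EnrichmentResult] = {}
    for si, (stage, peaks) in enumerate(sorted(peak_sets.items())):
        loci = [p.locus for p in peaks]
        observed = int(overlaps_any(windows, loci).sum())
        draws = np.empty(n_perm)
        for i in range(n_perm):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed),
                                       spawn_key=(si, i)))
            shuffled = shuffle_intervals(loci, layout, rng)
            draws[i] = overlaps_any(windows, shuffled).sum()
        results[stage] = summarize_null(observed, draws, n_perm, seed)
    return attach_fdr(results)
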