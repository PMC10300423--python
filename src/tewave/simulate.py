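"""Synthetic genome generator with planted effects and ground truth.

Emulates the downstream products of the ZGA multi-omics datasets the
analyses consume — gene/TE annotations, per-stage ATAC and Pol-II peak
sets, signal tracks, per-locus count matrices — at desk scale, with
every structure the methods assume planted and recorded in truth
tables:

* gene clusters (runs of >= 5 same-category genes, gaps < 500 kb);
* a focal "minor-wave" gene set, a configured fraction of which carries
  a MERVL within 100 bp of its TSS;
* full-length young LINE-1s, a fraction split into contiguous fragments
  (genomic gap 0-1 nt, consensus gap < 5 nt) to exercise joining, with
  promoter monomers on a subset;
* stage-specific intergenic ATAC peaks at the 3' ends of
  monomer-bearing LINE-1s, Pol-II peaks on monomers with known AUCs and
  stage membership, and negative-binomial counts with a LINE-1 group
  expressed only from a configured onset stage.

Identical config + seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (GenomeLayout, GenomicInterval, GeneRecord, SignalTrack,
                   TERecord, merge_intervals)
from .expression import CountsMatrix
from .peaks import PeakRecord
from .te import MonomerRecord

_MONOMER_TYPE = {"L1Md_A": "A", "L1Md_Gf": "Gf", "L1Md_Tf": "Tf"}

#: background (subfamily, class, family, count, length) mix; proportions
#: loosely follow the mm10 repeat landscape at toy scale
BACKGROUND_TES = (
    ("Lx", "LINE", "L1", 360, 900), ("Lx5", "LINE", "L1", 300, 700),
    ("L1M2", "LINE", "L1", 240, 800), ("L1_Mus3", "LINE", "L1", 200, 600),
    ("B1_Mus1", "SINE", "Alu", 420, 150), ("B2_Mm1a", "SINE", "B2", 300, 190),
    ("RSINE1", "SINE", "B4", 280, 160), ("MTA_Mm", "LTR", "MaLR", 330, 380),
    ("IAPEz-int", "LTR", "ERVK", 160, 1500), ("RLTR10", "LTR", "ERVK", 140, 450),
    ("RMER19B", "LTR", "ERVL", 120, 400), ("MER46C", "DNA", "TcMar-Tigger", 110, 250),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    # genes and clusters
    n_genes: int = 2000
    gene_len_range: tuple[int, int] = (1_000, 8_000)
    n_clusters: int = 30
    genes_per_cluster: int = 6
    n_background_categories: int = 400
    # focal (minor-wave) gene set and MERVL planting
    n_focal: int = 200
    focal_cluster_frac: float = 0.30
    mervl_adjacent_frac: float = 0.17
    n_mervl_background: int = 120
    mervl_length: int = 500
    # young LINE-1s
    n_line1_full: int = 160
    line1_length: int = 6_500
    fragmentation_prob: float = 0.5
    monomer_prob: float = 0.6
    monomer_length: int = 200
    # stages
    stages: tuple[str, ...] = ("preZGA", "early2C", "late2C", "eightC")
    designated_stage: str = "early2C"  # intergenic L1 3'-end ATAC peaks
    l1_onset_stage: str = "late2C"  # planted L1 group expressed from here
    # ATAC peaks
    genic_peaks_per_stage: int = 300
    intergenic_background_peaks: int = 60
    atac_peak_width: int = 300
    # Pol-II
    polii_early_prob: float = 0.75
    polii_late_given_early: float = 0.85
    polii_late_given_not: float = 0.30
    polii_eight_frac: float = 0.60
    polii_eight_from_earlier: float = 0.87
    n_decoy_polii_peaks: int = 80
    decoy_auc_fail_frac: float = 0.5
    # counts
    nb_dispersion: float = 0.1
    n_replicates: int = 2
    maternal_mean: float = 50.0
    focal_base_mean: float = 5.0
    focal_log2fc: float = 2.0
    l1_group_mean: float = 30.0
    l1_background_mean: float = 0.5
    te_background_mean: float = 2.0

    def __post_init__(self):
        for name in ("fragmentation_prob", "monomer_prob",
                     "mervl_adjacent_frac", "focal_cluster_frac",
                     "polii_early_prob", "polii_eight_from_earlier"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.designated_stage not in self.stages \
                or self.l1_onset_stage not in self.stages:
            raise ValueError("designated stages must appear in the stage list")


@dataclass
class SyntheticTruth:
    """Ground-truth tables consistent with the emitted annotation."""

    planted_clusters: list[tuple[str, ...]] = field(default_factory=list)
    focal_genes: list[str] = field(default_factory=list)
    mervl_adjacent_genes: list[str] = field(default_factory=list)
    fragment_map: dict[str, str] = field(default_factory=dict)
    full_length_l1: list[str] = field(default_factory=list)
    monomer_l1: list[str] = field(default_factory=list)
    l1_group: list[str] = field(default_factory=list)
    young_l1_universe: list[str] = field(default_factory=list)
    polii_membership: dict[str, set[str]] = field(default_factory=dict)
    auc_pass_peaks: list[str] = field(default_factory=list)
    auc_fail_peaks: list[str] = field(default_factory=list)


@dataclass
class SyntheticAnnotation:
    layout: GenomeLayout
    genes: list[GeneRecord]
    tes: list[TERecord]  # fragment-level, as a RepeatMasker table would be
    monomers: list[MonomerRecord]
    l1_full: list[TERecord]  # planted full-length elements (pre-split)
    truth: SyntheticTruth
    config: SimulationConfig


@dataclass
class SyntheticPeaks:
    atac: dict[str, list[PeakRecord]]
    polii: dict[str, list[PeakRecord]]
    polii_signal: dict[str, SignalTrack]


def _place_avoiding(rng, layout, length, forbidden_arrays, n,
                    self_margin: int | None = None, max_tries=200):
    """Uniform starts of ``length``-bp features avoiding forbidden zones.

    With ``self_margin`` set, accepted placements also repel each other
    by that many bp (keeps planted elements distinct loci).
    """
    chroms = list(layout.chrom_names)
    lens = np.array([layout.length(c) for c in chroms])
    out = []
    accepted: dict[str, list[tuple[int, int]]] = {}
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError("infeasible packing: genome too full")
        need = n - len(out)
        slots = lens - length + 1
        if (slots <= 0).all():
            raise ValueError("feature longer than every chromosome")
        probs = np.clip(slots, 0, None).astype(float)
        cidx = rng.choice(len(chroms), size=need, p=probs / probs.sum())
        starts = rng.integers(0, slots[cidx])
        for ci, s in zip(cidx, starts):
            chrom = chroms[ci]
            fs, fe = forbidden_arrays.get(chrom, (None, None))
            if fs is not None and len(fs):
                j = np.searchsorted(fe, s, side="right")
                if j < len(fs) and fs[j] < s + length:
                    continue
            if self_margin is not None and any(
                    s < pe + self_margin and ps - self_margin < s + length
                    for ps, pe in accepted.get(chrom, ())):
                continue
            out.append((chrom, int(s)))
            if self_margin is not None:
                accepted.setdefault(chrom, []).append((s, s + length))
            if len(out) == n:
                break
    return out


def _forbidden(intervals):
    merged = merge_intervals(intervals)
    per: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by.items():
        per[chrom] = (np.array([i.start for i in ivs]),
                      np.array([i.end for i in ivs]))
    return per


def simulate_genome_annotation(config: SimulationConfig = SimulationConfig()
                               ) -> SyntheticAnnotation:
    """Generate layout, genes, TE table, monomers and truth tables."""
    rng = np.random.default_rng(config.seed)
    chrom_names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    layout = GenomeLayout.from_dict(
        {c: config.chrom_length for c in chrom_names})
    truth = SyntheticTruth()

    # --- LINE-1 territories first (they must stay intergenic) ----------
    l1_sites = _place_avoiding(rng, layout, config.line1_length, {},
                               config.n_line1_full, self_margin=1000)
    l1_zone: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in chrom_names:
        spans = sorted((s, s + config.line1_length)
                       for c, s in l1_sites if c == chrom)
        l1_zone[chrom] = (np.array([p[0] for p in spans]),
                          np.array([p[1] for p in spans]))

    # --- genes: uniform starts, kept >= 3.5 kb away from LINE-1s -------
    per_chrom = rng.multinomial(config.n_genes,
                                np.full(config.n_chroms, 1 / config.n_chroms))
    genes: list[GeneRecord] = []
    gi = 0
    gene_buffer = 3_500  # keeps promoter/downstream windows off the L1s
    for chrom, n_on in zip(chrom_names, per_chrom):
        lo, hi = config.gene_len_range
        zs, ze = l1_zone[chrom]
        placed: list[tuple[int, int, str]] = []
        guard = 0
        while len(placed) < n_on:
            guard += 1
            if guard > 200:
                raise ValueError("infeasible packing: genome too full")
            need = n_on - len(placed)
            lengths = rng.integers(lo, hi + 1, size=2 * need)
            starts = rng.integers(0, config.chrom_length - hi, size=2 * need)
            strands = rng.choice(["+", "-"], size=2 * need)
            for s, L, st in zip(starts, lengths, strands):
                lo_edge, hi_edge = s - gene_buffer, s + L + gene_buffer
                if len(zs):
                    j = np.searchsorted(ze, lo_edge, side="right")
                    if j < len(zs) and zs[j] < hi_edge:
                        continue
                placed.append((int(s), int(L), str(st)))
                if len(placed) == n_on:
                    break
        placed.sort()
        for s, L, st in placed:
            gid = f"gene{gi:05d}"
            span = GenomicInterval(chrom, s, s + L, st, gid)
            # three-exon substructure with terminal UTRs
            exons = (GenomicInterval(chrom, s, s + 250, st),
                     GenomicInterval(chrom, s + L // 2 - 125,
                                     s + L // 2 + 125, st),
                     GenomicInterval(chrom, s + L - 250, s + L, st))
            head = GenomicInterval(chrom, s, s + 80, st)
            tail = GenomicInterval(chrom, s + L - 80, s + L, st)
            u5, u3 = (head, tail) if st == "+" else (tail, head)
            genes.append(GeneRecord(gid, span, None, exons, (u5,), (u3,)))
            gi += 1

    # --- planted clusters: runs of consecutive genes, own category -----
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.span.chrom, []).append(i)
    run = config.genes_per_cluster
    candidates = []
    for chrom, idxs in by_chrom.items():
        for k in range(0, len(idxs) - run, run + 2):  # disjoint, spaced runs
            block = idxs[k:k + run]
            gaps = [genes[block[j + 1]].span.start - genes[block[j]].span.end
                    for j in range(run - 1)]
            if all(g <= 500_000 for g in gaps):
                candidates.append(block)
    if len(candidates) < config.n_clusters:
        raise ValueError("infeasible packing: not enough cluster slots")
    chosen = rng.choice(len(candidates), size=config.n_clusters, replace=False)
    categories = np.array(
        [f"bg{rng.integers(config.n_background_categories):02d}"
         for _ in genes], dtype=object)
    for ci, slot in enumerate(sorted(chosen)):
        block = candidates[slot]
        categories[block] = f"dom{ci:02d}"
        truth.planted_clusters.append(
            tuple(genes[i].gene_id for i in block))
    genes = [replace(g, category=str(c)) for g, c in zip(genes, categories)]

    # --- focal gene set: a planted in-cluster share --------------------
    in_cluster = [i for cl in truth.planted_clusters
                  for i, g in enumerate(genes) if g.gene_id in cl]
    in_cluster = sorted(set(in_cluster))
    out_cluster = sorted(set(range(len(genes))) - set(in_cluster))
    n_in = int(round(config.n_focal * config.focal_cluster_frac))
    n_out = config.n_focal - n_in
    focal_idx = sorted(
        list(rng.choice(in_cluster, size=n_in, replace=False))
        + list(rng.choice(out_cluster, size=n_out, replace=False)))
    truth.focal_genes = [genes[i].gene_id for i in focal_idx]

    # --- TEs: background mix + MERVLs + young LINE-1s ------------------
    tes: list[TERecord] = []
    tid = 0

    def emit(chrom, start, end, strand, name, subfam, cls, fam, cs, ce):
        nonlocal tid
        tes.append(TERecord(
            GenomicInterval(chrom, start, end, strand, name),
            subfamily=subfam, te_class=cls, family=fam,
            consensus_start=cs, consensus_end=ce, source_ids=(name,)))
        tid += 1

    for subfam, cls, fam, count, length in BACKGROUND_TES:
        placements = _place_avoiding(rng, layout, length, {}, count)
        for chrom, s in placements:
            strand = str(rng.choice(["+", "-"]))
            emit(chrom, s, s + length, strand, f"te{tid:05d}",
                 subfam, cls, fam, 1, length)

    # background MERVLs, uniform
    mervl_names = ["MERVL-int", "MT2_Mm"]
    for chrom, s in _place_avoiding(rng, layout, config.mervl_length, {},
                                    config.n_mervl_background):
        strand = str(rng.choice(["+", "-"]))
        emit(chrom, s, s + config.mervl_length, strand, f"te{tid:05d}",
             str(rng.choice(mervl_names)), "LTR", "ERVL", 1,
             config.mervl_length)

    # planted MERVLs within 100 bp of focal TSSs
    n_adj = int(round(config.n_focal * config.mervl_adjacent_frac))
    adj_idx = rng.choice(focal_idx, size=n_adj, replace=False)
    for i in sorted(adj_idx):
        g = genes[i]
        d = int(rng.integers(10, 91))  # TSS-to-TE edge distance, < 100
        if g.span.strand == "+":
            tss = g.span.start
            s = max(0, tss - d - config.mervl_length)
        else:
            tss = g.span.end - 1
            s = min(tss + d, config.chrom_length - config.mervl_length)
        emit(g.span.chrom, s, s + config.mervl_length,
             str(rng.choice(["+", "-"])), f"te{tid:05d}",
             str(rng.choice(mervl_names)), "LTR", "ERVL", 1,
             config.mervl_length)
        truth.mervl_adjacent_genes.append(g.gene_id)

    # young full-length LINE-1s on the pre-reserved intergenic territories
    young_names = list(_MONOMER_TYPE)
    l1_full: list[TERecord] = []
    monomers: list[MonomerRecord] = []
    for k, (chrom, s) in enumerate(l1_sites):
        subfam = str(rng.choice(young_names))
        strand = str(rng.choice(["+", "-"]))
        L = config.line1_length
        full_id = f"L1_{k:03d}"
        cons_start = int(rng.integers(1, 300))
        full = TERecord(GenomicInterval(chrom, s, s + L, strand, full_id),
                        subfamily=subfam, te_class="LINE", family="L1",
                        consensus_start=cons_start,
                        consensus_end=cons_start + L - 1,
                        source_ids=(full_id,))
        l1_full.append(full)
        truth.full_length_l1.append(full_id)

        if rng.random() < config.fragmentation_prob:
            n_frag = int(rng.integers(2, 4))
            while True:  # fragments at least 500 bp each
                cuts = np.sort(rng.choice(
                    np.arange(500, L - 500), size=n_frag - 1, replace=False))
                if n_frag == 2 or int(np.diff(cuts).min()) >= 500:
                    break
            bounds = [0, *cuts.tolist(), L]
            for f in range(n_frag):
                truth.fragment_map[f"{full_id}.f{f}"] = full_id
            genomic_gaps = rng.integers(0, 2, size=n_frag - 1)
            cons_gaps = rng.integers(1, 5, size=n_frag - 1)
            frag_lens = np.diff(bounds)
            gstart = s
            frag_spans = []
            for f in range(n_frag):
                frag_spans.append((gstart, gstart + int(frag_lens[f])))
                if f < n_frag - 1:
                    gstart = frag_spans[-1][1] + int(genomic_gaps[f])
            # consensus coordinates per fragment, 5'->3'
            cons_spans = []
            cpos = cons_start
            for f in range(n_frag):
                cons_spans.append((cpos, cpos + int(frag_lens[f]) - 1))
                if f < n_frag - 1:
                    cpos = cons_spans[-1][1] + int(cons_gaps[f])
            if strand == "-":
                cons_spans = cons_spans[::-1]
            for f in range(n_frag):
                fid = f"{full_id}.f{f}"
                emit(chrom, frag_spans[f][0], frag_spans[f][1], strand, fid,
                     subfam, "LINE", "L1", cons_spans[f][0], cons_spans[f][1])
        else:
            emit(chrom, s, s + L, strand, full_id, subfam, "LINE", "L1",
                 cons_start, cons_start + L - 1)
            truth.fragment_map[full_id] = full_id

        if rng.random() < config.monomer_prob:
            ml = config.monomer_length
            if strand == "+":
                span = GenomicInterval(chrom, s, s + ml, strand,
                                       f"mono_{full_id}")
            else:
                span = GenomicInterval(chrom, s + L - ml, s + L, strand,
                                       f"mono_{full_id}")
            monomers.append(MonomerRecord(span, _MONOMER_TYPE[subfam]))
            truth.monomer_l1.append(full_id)

    truth.young_l1_universe = list(truth.full_length_l1)
    truth.l1_group = list(truth.monomer_l1)
    tes.sort(key=lambda t: (t.locus.chrom, t.locus.start, t.locus.end))
    return SyntheticAnnotation(layout, genes, tes, monomers, l1_full, truth,
                               config)


def simulate_peaks_and_signal(ann: SyntheticAnnotation) -> SyntheticPeaks:
    """Per-stage ATAC and Pol-II peak sets plus Pol-II signal tracks."""
    config = ann.config
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(1,)))
    truth = ann.truth
    layout = ann.layout
    full_by_id = {t.te_id: t for t in ann.l1_full}
    mono_by_l1 = {m.locus.name.removeprefix("mono_"): m
                  for m in ann.monomers}

    atac: dict[str, list[PeakRecord]] = {}
    w = config.atac_peak_width
    gene_pool = ann.genes
    forbidden = _forbidden([
        GenomicInterval(g.span.chrom, max(0, g.span.start - 3_500),
                        min(config.chrom_length, g.span.end + 3_500))
        for g in gene_pool] + [t.locus for t in ann.l1_full])
    for stage in config.stages:
        peaks: list[PeakRecord] = []
        pick = rng.choice(len(gene_pool), size=config.genic_peaks_per_stage,
                          replace=False)
        for j in sorted(pick):
            g = gene_pool[j]
            tss = g.span.start if g.span.strand == "+" else g.span.end - 1
            s = max(0, tss - w // 2)
            e = min(layout.length(g.span.chrom), s + w)
            peaks.append(PeakRecord(
                GenomicInterval(g.span.chrom, s, e, ".",
                                f"atac_{stage}_g{j}"), stage))
        for k, (chrom, s) in enumerate(_place_avoiding(
                rng, layout, w, forbidden,
                config.intergenic_background_peaks)):
            peaks.append(PeakRecord(
                GenomicInterval(chrom, s, s + w, ".",
                                f"atac_{stage}_bg{k}"), stage))
        if stage == config.designated_stage:
            for l1_id in truth.monomer_l1:
                t = full_by_id[l1_id]
                end3 = t.locus.end if t.locus.strand == "+" else t.locus.start
                s = max(0, end3 - w // 2)
                e = min(layout.length(t.locus.chrom), s + w)
                peaks.append(PeakRecord(
                    GenomicInterval(t.locus.chrom, s, e, ".",
                                    f"atac_{stage}_{l1_id}"), stage))
        atac[stage] = peaks

    # --- Pol-II: monomer-bound sets with known stage membership --------
    mono_ids = list(truth.monomer_l1)
    n_mono = len(mono_ids)
    early = rng.random(n_mono) < config.polii_early_prob
    late = np.where(early,
                    rng.random(n_mono) < config.polii_late_given_early,
                    rng.random(n_mono) < config.polii_late_given_not)
    earlier = early | late
    n8 = int(round(config.polii_eight_frac * n_mono))
    n8_old = min(int(round(config.polii_eight_from_earlier * n8)),
                 int(earlier.sum()))
    n8_new = min(n8 - n8_old, int((~earlier).sum()))
    eight = np.zeros(n_mono, dtype=bool)
    old_idx = np.flatnonzero(earlier)
    new_idx = np.flatnonzero(~earlier)
    eight[rng.choice(old_idx, size=n8_old, replace=False)] = True
    if n8_new:
        eight[rng.choice(new_idx, size=n8_new, replace=False)] = True

    stage_sets = {"early2C": early, "late2C": late, "eightC": eight}
    polii: dict[str, list[PeakRecord]] = {s: [] for s in config.stages}
    signal_steps: dict[str, list] = {s: [] for s in config.stages}
    truth.polii_membership = {}
    for stage in config.stages:
        mask = stage_sets.get(stage)
        if mask is None:
            truth.polii_membership[stage] = set()
            continue
        bound = {mono_ids[i] for i in np.flatnonzero(mask)}
        truth.polii_membership[stage] = bound
        for l1_id in sorted(bound):
            mono = mono_by_l1[l1_id]
            iv = replace(mono.locus, name=f"polii_{stage}_{l1_id}")
            auc = float(rng.uniform(600, 3000))
            value = auc / iv.length
            polii[stage].append(PeakRecord(iv, stage))
            signal_steps[stage].append((GenomicInterval(
                iv.chrom, iv.start, iv.end), value))
            truth.auc_pass_peaks.append(iv.name)

    # decoy Pol-II peaks exercising the AUC filter
    decoys = _place_avoiding(rng, layout, w, forbidden,
                             config.n_decoy_polii_peaks, self_margin=1)
    decoy_stage = config.designated_stage
    for k, (chrom, s) in enumerate(decoys):
        iv = GenomicInterval(chrom, s, s + w, ".",
                             f"polii_decoy{k}")
        fail = rng.random() < config.decoy_auc_fail_frac
        auc = float(rng.uniform(100, 450)) if fail \
            else float(rng.uniform(600, 3000))
        polii[decoy_stage].append(PeakRecord(iv, decoy_stage))
        signal_steps[decoy_stage].append(
            (GenomicInterval(chrom, s, s + w), auc / w))
        (truth.auc_fail_peaks if fail else truth.auc_pass_peaks).append(
            iv.name)

    polii_signal = {s: SignalTrack(steps)
                    for s, steps in signal_steps.items()}
    return SyntheticPeaks(atac, polii, polii_signal)


def simulate_counts(ann: SyntheticAnnotation) -> CountsMatrix:
    """Negative-binomial counts for genes and TE loci (fragment level)."""
    config = ann.config
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(2,)))
    truth = ann.truth
    stages = config.stages
    onset = stages.index(config.l1_onset_stage)
    focal = set(truth.focal_genes)
    group = set(truth.l1_group)
    minor_on = stages.index(config.designated_stage)

    feature_ids: list[str] = []
    means = []  # per feature, per stage
    for g in ann.genes:
        if g.gene_id in focal:
            mu = [config.focal_base_mean *
                  (2 ** config.focal_log2fc if si >= minor_on else 1.0)
                  for si in range(len(stages))]
        else:
            mu = [config.maternal_mean] * len(stages)
        feature_ids.append(g.gene_id)
        means.append(mu)

    # full-length L1 means, split over fragments below
    l1_mean: dict[str, list[float]] = {}
    for l1_id in truth.full_length_l1:
        if l1_id in group:
            mu = [config.l1_group_mean if si >= onset
                  else config.l1_background_mean
                  for si in range(len(stages))]
        else:
            mu = [config.l1_background_mean] * len(stages)
        l1_mean[l1_id] = mu

    frag_of: dict[str, list[TERecord]] = {}
    for t in ann.tes:
        full_id = truth.fragment_map.get(t.te_id)
        if full_id is not None:
            frag_of.setdefault(full_id, []).append(t)
        else:
            feature_ids.append(t.te_id)
            means.append([config.te_background_mean] * len(stages))

    samples = [f"{st}_r{r + 1}" for st in stages
               for r in range(config.n_replicates)]
    stage_of = pd.Series([s.rsplit("_r", 1)[0] for s in samples],
                         index=samples)
    mean_mat = np.array(means)  # simple features x stages

    def draw(mu_arr):
        if config.nb_dispersion < 1e-9:
            return rng.poisson(mu_arr)
        r = 1.0 / config.nb_dispersion
        return rng.negative_binomial(r, r / (r + np.maximum(mu_arr, 1e-12)))

    data = {}
    for si, st in enumerate(stages):
        for rep in range(config.n_replicates):
            data[f"{st}_r{rep + 1}"] = draw(mean_mat[:, si])
    counts = pd.DataFrame(data, index=feature_ids)

    # fragment counts: draw full-element totals, split by fragment length
    frag_rows = {}
    for l1_id, frags in sorted(frag_of.items()):
        frags = sorted(frags, key=lambda t: t.locus.start)
        lens = np.array([t.locus.length for t in frags], dtype=float)
        p = lens / lens.sum()
        for si, st in enumerate(stages):
            for rep in range(config.n_replicates):
                total = int(draw(np.array([l1_mean[l1_id][si]]))[0])
                split = rng.multinomial(total, p)
                for t, c in zip(frags, split):
                    frag_rows.setdefault(t.te_id, {})[
                        f"{st}_r{rep + 1}"] = int(c)
    if frag_rows:
        frag_df = pd.DataFrame.from_dict(frag_rows, orient="index")
        frag_df = frag_df[counts.columns]
        counts = pd.concat([counts, frag_df])
    return CountsMatrix(counts, stage_of)
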