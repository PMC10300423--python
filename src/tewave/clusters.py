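"""Gene-cluster detection and cluster-overlap enrichment.

A gene cluster is a run of at least ``n_min`` consecutive genes sharing
a functional-domain category, with edge-to-edge gaps of at most
``max_dist`` bp (the ClusterScan ``-n 5 -d 500,000`` semantics).
Enrichment of a focal gene set inside clusters is assessed against a
null built by shuffling cluster coordinates genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (GenomeLayout, GenomicInterval, GeneRecord,
                   shuffle_intervals)
from .stats import EnrichmentResult, summarize_null


@dataclass(frozen=True)
class GeneCluster:
    locus: GenomicInterval  # unstranded hull, first start to last end
    category: str
    member_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.member_ids) < 2:
            raise ValueError("a cluster needs at least two members")


def find_clusters(genes: Sequence[GeneRecord], n_min: int = 5,
                  max_dist: int = 500_000
                  ) -> tuple[list[GeneCluster], list[str]]:
    """Chain same-category genes per chromosome into clusters.

    Consecutive (genomically sorted) genes of one category chain while
    ``next.start - prev.end <= max_dist``; chains with >= ``n_min``
    members become clusters, chains of exactly one gene are reported as
    singletons.  A gene with a category may join one chain per category.
    Clusters of different categories may overlap.
    """
    by_key: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        if g.category is None:
            continue
        by_key.setdefault((g.span.chrom, g.category), []).append(g)

    clusters: list[GeneCluster] = []
    singletons: list[str] = []
    for (chrom, category), members in sorted(by_key.items()):
        members.sort(key=lambda g: (g.span.start, g.span.end))
        chain: list[GeneRecord] = []

        def flush():
            if len(chain) >= n_min:
                hull = GenomicInterval(
                    chrom, min(g.span.start for g in chain),
                    max(g.span.end for g in chain), ".",
                    f"cluster_{category}_{chain[0].gene_id}")
                clusters.append(GeneCluster(
                    hull, category, tuple(g.gene_id for g in chain)))
            elif len(chain) == 1:
                singletons.append(chain[0].gene_id)
            chain.clear()

        for g in members:
            if chain and g.span.start - chain[-1].span.end > max_dist:
                flush()
            chain.append(g)
        flush()
    clusters.sort(key=lambda c: (c.locus.chrom, c.locus.start))
    return clusters, singletons


def _gene_arrays(genes: Sequence[GeneRecord]):
    """Per-chromosome sorted (starts, ends) arrays for fast counting."""
    per: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        per.setdefault(g.span.chrom, []).append((g.span.start, g.span.end))
    out = {}
    for chrom, pairs in per.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs], dtype=np.int64)
        ends = np.array([p[1] for p in pairs], dtype=np.int64)
        out[chrom] = (starts, ends, int((ends - starts).max()))
    return out


def _count_genes_in_intervals(gene_arrays, intervals, min_frac: float
                              ) -> np.ndarray:
    """Boolean per gene (in gene_arrays order): >= min_frac inside some
    interval.  The fraction is evaluated per (gene, interval) pair."""
    flags = {chrom: np.zeros(len(arr[0]), dtype=bool)
             for chrom, arr in gene_arrays.items()}
    for iv in intervals:
        arr = gene_arrays.get(iv.chrom)
        if arr is None:
            continue
        starts, ends, maxlen = arr
        lo = np.searchsorted(starts, iv.start - maxlen, side="left")
        hi = np.searchsorted(starts, iv.end, side="left")
        if hi <= lo:
            continue
        s, e = starts[lo:hi], ends[lo:hi]
        ov = np.minimum(e, iv.end) - np.maximum(s, iv.start)
        need = np.maximum(min_frac * (e - s), 1)  # at least 1 bp overlap
        flags[iv.chrom][lo:hi] |= ov >= need
    return np.concatenate([flags[c] for c in sorted(flags)]) \
        if flags else np.zeros(0, dtype=bool)


def genes_in_clusters(genes: Sequence[GeneRecord],
                      clusters: Sequence[GeneCluster | GenomicInterval],
                      min_frac: float = 0.5) -> tuple[int, list[str]]:
    """Count genes with >= ``min_frac`` of their span inside one cluster.

    The fraction is measured against each cluster separately (a gene
    straddling two adjacent clusters with 30% in each does not count);
    a gene counts once however many clusters contain it.
    """
    hulls = [c.locus if isinstance(c, GeneCluster) else c for c in clusters]
    arrays = _gene_arrays(genes) if genes else {}
    if not arrays:
        return 0, []
    flags = _count_genes_in_intervals(arrays, hulls, min_frac)
    # map flags (per-chrom sorted order) back to gene ids
    ids: list[str] = []
    per: dict[str, list[GeneRecord]] = {}
    for g in genes:
        per.setdefault(g.span.chrom, []).append(g)
    flat: list[str] = []
    for chrom in sorted(per):
        members = sorted(per[chrom], key=lambda g: (g.span.start, g.span.end))
        flat.extend(g.gene_id for g in members)
    ids = [gid for gid, f in zip(flat, flags) if f]
    return int(flags.sum()), ids


def cluster_enrichment(gene_set: Sequence[GeneRecord],
                       clusters: Sequence[GeneCluster],
                       layout: GenomeLayout, n_perm: int = 1000,
                       seed: int = 0, min_frac: float = 0.5
                       ) -> EnrichmentResult:
    """Is a focal gene set enriched inside gene clusters?

    Observed statistic: number of focal genes with >= ``min_frac`` of
    their span inside a cluster hull.  Null: the same count against
    cluster hulls shuffled genome-wide, ``n_perm`` times.
    """
    hulls = [c.locus if isinstance(c, GeneCluster) else c for c in clusters]
    arrays = _gene_arrays(gene_set)
    observed = int(_count_genes_in_intervals(arrays, hulls, min_frac).sum())
    draws = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(i,)))
        shuffled = shuffle_intervals(hulls, layout, rng)
        draws[i] = _count_genes_in_intervals(arrays, shuffled,
                                             min_frac).sum()
    return summarize_null(observed, draws, n_perm, seed)
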