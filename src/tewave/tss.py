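"""TE-subfamily enrichment near the TSSs of a focal gene set.

The TSS of each gene (its strand-aware 5'-most base) is extended by a
flank on both sides; a gene "hits" a subfamily when its extended TSS
window overlaps at least one TE locus of that subfamily (one count per
gene per subfamily however many TEs fall in the window).  Enrichment of
a focal gene set is assessed against equal-size random gene sets.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import (GenomeLayout, GeneRecord, TERecord, extend_clip,
                   five_prime_point, intersect_fraction, derive_rng)
from .stats import EnrichmentResult, attach_fdr, summarize_null


def tss_hit_matrix(genes: Sequence[GeneRecord], tes: Sequence[TERecord],
                   layout: GenomeLayout, flank: int = 100) -> pd.DataFrame:
    """Boolean genes x subfamilies table of extended-TSS overlaps."""
    windows = [extend_clip(five_prime_point(g), flank, flank, layout)
               for g in genes]
    subfams = sorted({t.subfamily for t in tes})
    col = {s: j for j, s in enumerate(subfams)}
    mat = np.zeros((len(genes), len(subfams)), dtype=bool)
    for rec in intersect_fraction(windows, tes, 0.0):
        mat[rec.a_index, col[tes[rec.b_index].subfamily]] = True
    return pd.DataFrame(mat, index=[g.gene_id for g in genes],
                        columns=subfams)


def tss_te_overlap_counts(gene_set: Sequence[GeneRecord],
                          tes: Sequence[TERecord], layout: GenomeLayout,
                          flank: int = 100) -> pd.Series:
    """Per-subfamily count of genes whose extended TSS overlaps >= 1 TE."""
    hits = tss_hit_matrix(gene_set, tes, layout, flank)
    return hits.sum(axis=0)


def tss_enrichment_test(focal_genes: Sequence[GeneRecord],
                        all_genes: Sequence[GeneRecord],
                        tes: Sequence[TERecord], layout: GenomeLayout,
                        flank: int = 100, n_perm: int = 1000, seed: int = 0,
                        exclude_focal: bool = False,
                        hit_matrix: pd.DataFrame | None = None
                        ) -> dict[str, EnrichmentResult]:
    """Per-subfamily enrichment of TEs near focal-gene TSSs.

    The null resamples equal-size gene sets without replacement from
    the full annotation (including the focal genes unless
    ``exclude_focal``); BH FDR is applied across subfamilies.
    ``hit_matrix`` may carry a precomputed :func:`tss_hit_matrix` for
    the same genes/TEs/flank to amortise repeated testing.
    """
    if len(focal_genes) > len(all_genes):
        raise ValueError("focal set larger than the gene universe")
    focal_ids = {g.gene_id for g in focal_genes}
    hits = hit_matrix if hit_matrix is not None \
        else tss_hit_matrix(all_genes, tes, layout, flank)
    mat = hits.to_numpy()
    universe_idx = np.arange(len(all_genes))
    if exclude_focal:
        universe_idx = np.array(
            [i for i, g in enumerate(all_genes)
             if g.gene_id not in focal_ids])
        if len(focal_genes) > len(universe_idx):
            raise ValueError("focal set larger than the exclusion universe")
    focal_rows = np.array([i for i, g in enumerate(all_genes)
                           if g.gene_id in focal_ids])
    if len(focal_rows) != len(focal_genes):
        raise ValueError("focal genes must be a subset of all_genes")
    observed = mat[focal_rows].sum(axis=0)

    k = len(focal_rows)
    draws = np.empty((n_perm, mat.shape[1]))
    for i in range(n_perm):
        rng = derive_rng(seed, i)
        sample = rng.choice(universe_idx, size=k, replace=False)
        draws[i] = mat[sample].sum(axis=0)

    results = {
        subfam: summarize_null(float(observed[j]), draws[:, j], n_perm, seed)
        for j, subfam in enumerate(hits.columns)
    }
    return attach_fdr(results)
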