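# tewave

Interval-permutation statistics and transposable-element (TE) annotation
for studying **zygotic genome activation (ZGA)** in the mouse embryo.

At ZGA, two retrotransposon classes drive distinct transcriptional
programs: **MERVL** elements act as alternative promoters for
minor-wave genes in gene-dense compartments, while evolutionary young
**LINE-1** elements (subfamilies A, Gf, Tf) open chromatin and recruit
Pol II from intergenic regions. Characterising these dynamics from
downstream sequencing products (RepeatMasker tables, GTF gene models,
per-stage ATAC/Stacc-seq peak sets, bedGraph signal, per-locus count
matrices) requires a family of bespoke procedures that this package
implements as a tested, reusable library:

- **Interval algebra** on 0-based half-open coordinates: fractional
  intersection (`bedtools intersect -f` semantics), strand-aware 5'
  points, clipping extensions, uniform genome-wide shuffling.
- **Permutation statistics**: for an observed statistic \(s\) and null
  draws \(s_1,\dots,s_B\),
  \(z = (s - \hat\mu)/\hat\sigma\), the two-sided normal
  \(p = 2\,\Phi(-|z|)\), and the exact empirical
  \(p = (\#\{s_i \ge s\} + 1)/(B + 1)\); Benjamini–Hochberg FDR across
  each test family; pooled two-proportion z-tests.
- **LINE-1 defragmentation**: RepeatMasker rows belonging to one
  element are chained when they share a subfamily and strand, are less
  than 2 nt apart on the genome, and represent portions less than 5 nt
  apart on the subfamily consensus (strand-aware ordering).
- **Promoter-monomer association**: a monomer is tied to the nearest
  same-strand LINE-1 5' start it overlaps or begins at most 100 nt
  downstream of.
- **Peak analysis**: length (> 10 nt) and AUC (> 500) filters,
  ChIPseeker-priority genic annotation (promoter ±3 kb > 5'UTR > 3'UTR
  > exon > intron > downstream > intergenic), intergenic-peak-to-TE
  assignment (≥ 50% of the peak, longest intersection wins), and
  per-stage set membership ("UpSet") counts.
- **Gene clusters**: runs of ≥ 5 consecutive same-category genes with
  inter-gene gaps ≤ 500 kb, plus shuffled-cluster enrichment of a focal
  gene set.
- **TSS enrichment**: per-subfamily counts of genes whose TSS ± 100 nt
  window touches a TE, against equal-size random gene sets.
- **Metagenes**: scaled-region binary-coverage (bin = 1 iff ≥ 50%
  covered, ×100) and mean-signal profiles with fixed flanks; signal
  masking outside peaks padded by 1 kb.
- **Expression**: TMM normalization (edgeR-equivalent, verified against
  it), summing counts of joined LINE-1 fragments, and group-vs-random
  LINE-1 expression tests per developmental stage.
- **Synthetic data**: a deterministic toy genome (2 × 10 Mb) with
  planted clusters, MERVL-adjacent focal TSSs, fragmented young LINE-1s
  with monomers, stage-specific 3'-end ATAC peaks, Pol-II peaks with
  known AUCs and stage membership, and negative-binomial counts — with
  ground-truth tables, so every procedure is testable end to end
  without downloads.

## Worked example

The defragmentation rule applied to two real annotation rows — an
L1Md_A annotated as chr1:3037726–3043047 (consensus 279–5,586) and
chr1:3043047–3044040 (consensus 5,587–6,580):

```python
from tewave import GenomicInterval, join_line1_fragments
from tewave.core import TERecord

frags = [
    TERecord(GenomicInterval("chr1", 3037726, 3043047, "+", "a"),
             subfamily="L1Md_A", family="L1", te_class="LINE",
             consensus_start=279, consensus_end=5586, source_ids=("a",)),
    TERecord(GenomicInterval("chr1", 3043047, 3044040, "+", "b"),
             subfamily="L1Md_A", family="L1", te_class="LINE",
             consensus_start=5587, consensus_end=6580, source_ids=("b",)),
]
joined, join_map = join_line1_fragments(frags)
print(joined[0].locus, joined[0].consensus_start, joined[0].consensus_end)
```

prints

```
chr1:3037726-3044040(+) 279 6580
```

one element spanning both rows (genomic gap 0 < 2, consensus gap
5,587 − 5,586 = 1 < 5) whose consensus span is the union of the two
portions.

Running the whole synthetic analysis:

```sh
tewave simulate --seed 3 --outdir run/
```

writes the annotation, per-stage peak sets, count matrix and every
analysis table into `run/`. With the default configuration the run
reports (see `run/manifest.json` and the TSVs):

- `cluster_genes_observed: 64` of 200 focal genes inside gene clusters
  (32%), against a shuffled-cluster expectation of ~14.6 (z ≈ 11.8) —
  the planted cluster enrichment;
- `tss_enrichment.tsv` flags only the MERVL names (`MERVL-int`,
  `MT2_Mm`) at FDR < 0.05 — the planted TSS-proximity effect;
- `eightC_bound_earlier_fraction: 0.864` — of the monomers bound by
  Pol II at the 8-cell stage, 86% were already bound at the early/late
  2-cell stages (the simulation plants this stalling pattern at a
  nominal 87%, realised as 51/59 here by integer rounding);
- `l1_group_expression.tsv` turns significant exactly from the
  configured onset stage (`late2C`) onward.

## CLI

`tewave` exposes each step as a subcommand: `convert`, `validate`,
`simulate`, `join-l1`, `monomers`, `annotate-peaks`, `clusters`,
`tss-enrich`, `polii-enrich`, `metagene`, `mask-signal`,
`expr-compare`, and `run` (full pipeline from a YAML config with a
checksummed manifest). See `tewave COMMAND --help`.
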