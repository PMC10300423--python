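# Methods

This note documents the models and procedures implemented in `tewave`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot show.

## Coordinates and interval algebra

All coordinates are 0-based half-open internally; GTF (1-based closed)
and RepeatMasker consensus columns are converted at the I/O boundary
only. A pair (a, b) is reported by `intersect_fraction` when
`overlap_bp / len(a) >= min_frac_a`, with `min_frac_a = 0` meaning any
positive overlap — the `bedtools intersect [-f]` semantics with the
fraction applied to the a-operand. Records on chromosomes absent from
the genome layout are dropped with a warning rather than an error,
mirroring the usual exclusion of scaffolds.

`shuffle_intervals` re-places each interval uniformly over **all**
genome positions where it fits entirely: a chromosome is chosen with
probability proportional to its number of valid start positions
(length − L + 1) and the start uniformly within them. This is the exact
version of length-proportional chromosome choice; the two differ only
by O(L/chrom-length). No exclusion regions are applied by default (a
`same-chromosome` mode exists as a sensitivity option). Seeds are
explicit everywhere; per-permutation generators are derived from the
master seed by counter (`SeedSequence(entropy=seed, spawn_key=(i,))`),
so results are reproducible and order-independent.

## Permutation statistics

Every enrichment test reports, for observed statistic s and null draws
s₁…s_B: the null mean and SD, z = (s − μ̂)/σ̂, the two-sided normal
p = 2Φ(−|z|), and the empirical upper-tail p = (#{sᵢ ≥ s} + 1)/(B + 1).
When the null is degenerate (σ̂ at floating-point rounding scale), z is
0 with p = 1 if the observed equals the null value, otherwise z is
reported as unset and the empirical p is used.

**Family-wise correction uses the empirical p.** For the families
corrected together (TE subfamilies in the TSS test, stages in the
expression and Pol-II tests), BH-FDR is computed on the empirical
permutation p-values and those become the headline `p`. Rationale: the
overlap counts involved are small and discrete; the normal
approximation is anti-conservative there (its upper tail understates
the lattice mass and we measured ~20% per-run probability of a spurious
subfamily at FDR < 0.05 on the synthetic genome), while empirical
permutation p-values are sub-uniform under the null by construction.
The z and normal p are still reported descriptively. A consequence is
that the number of permutations bounds the smallest attainable p at
1/(B+1): B must be sized to the family (B = 1000 by default; B < ~350
cannot reach FDR < 0.05 in a 17-member family).

**Calibration.** Drawing the observed input from a test's own null —
random gene sets for the TSS test, random feature sets for the
expression test, an independently shuffled cluster placement for the
cluster test — rejects at |z| > 1.96 in 5.0–5.4% of 2,000 trials
(the residual excess over 5% is the t-versus-normal effect of
estimating μ, σ from 150 draws).

**A caveat specific to coordinate-shuffle nulls.** The cluster test
compares a *fixed* focal gene set against *shuffled cluster
coordinates*. This null is not exchangeable with resampling the focal
set: on the synthetic genome, uniformly drawn focal sets reject at ~18%
(the LINE-1 territories are gene deserts, so shuffled hulls catch
systematically fewer genes than real, gene-anchored hulls), and even on
a homogeneous genome the bias persists in the opposite direction
(random windows catch partially overlapping edge genes that real
cluster hulls, built from whole gene runs, exclude). This is a property
of the method, worth keeping in mind when interpreting small cluster
enrichments; large planted effects (30% vs ~8%, z ≈ 11) are far outside
this bias.

The two-proportion z-test is the pooled-variance normal test; a pooled
proportion of exactly 0 or 1 carries no variance and returns (0, 1).

## LINE-1 defragmentation

RepeatMasker often splits one LINE-1 into several rows. Rows are
chained transitively when they (1) share the subfamily, chromosome and
strand, (2) are less than 2 nt apart on the genome (half-open
difference `next.start − prev.end` in {0, 1}; negative, i.e.
overlapping, rows are never joined), and (3) represent portions less
than 5 nt apart on the subfamily consensus. The consensus gap is
evaluated in the 5'→3' strand sense: for minus-strand elements the
genomically later row must carry the *smaller* consensus coordinates —
the only ordering consistent with LINE-1 structure. Chaining runs
within (chromosome, strand, subfamily) groups so that an interleaved
element of another subfamily (e.g. a SINE inserted at the junction of
the annotation) cannot break a chain. The joined record spans the
fragments' hull, carries the union of consensus spans, and remembers
its source row ids; the operation is idempotent.

Monomer association follows `bedtools closest -s`: a monomer is tied to
the nearest same-strand LINE-1 5' start that it overlaps or begins no
more than 100 nt downstream (3'-ward in the strand sense by default; a
`downstream_ref` flag switches to reference-coordinate downstream to
mirror `-D ref` literally). Ties between equidistant starts break on
the smaller genomic start.

## Peak analysis

Peaks are kept iff strictly longer than 10 nt, and (for Pol-II binding
sites) iff the area under the signal curve within the peak —
Σ value × bp over bedGraph steps — strictly exceeds 500. Genic
annotation resolves against the union gene model with the ChIPseeker
priority order; the promoter is TSS ± 3 kb, downstream is a 3-kb window
3'-ward of the gene end (ChIPseeker's default reporting range), and a
peak overlapping a gene span at non-exonic bases only is intronic.
Intergenic peaks are assigned to at most one TE: qualifying requires
≥ 50% of the *peak* inside the TE (the a-operand of the quoted
command), the longest intersection wins, ties break on the smaller TE
start.

## Clusters, TSS enrichment, metagenes

Cluster chaining measures gaps edge-to-edge (`next.start − prev.end ≤
500,000`), the clusterdist semantics of the cited detection tool; runs
of ≥ 5 same-category genes become clusters and their unstranded hull is
used downstream. A gene counts as in-cluster when ≥ 50% of its span
lies within a single hull (fractions do not add across adjacent hulls),
and counts once regardless of how many hulls contain it.

The TSS test extends each gene's 5'-most nucleotide (gene-level, not
per-transcript) by ±100 nt and counts, per subfamily, genes whose
window touches ≥ 1 TE locus (capped at one per gene per subfamily).
The null resamples equal-size gene sets from the full annotation,
including the focal genes (exclusion available as an option).

Metagene bodies are split into integer-bp bins with the remainder
spread over the trailing bins; flanks are fixed-width. Minus-strand
regions are computed in reference orientation and reversed, so bins
always run 5'→3'. In binary mode a bin scores 1 iff ≥ 50% of its
(nominal) width is covered by the element set — bases clipped off the
chromosome count as uncovered — and column means ×100 give the percent
of regions covered per position. Signal mode averages bedGraph values
per bin (scale-regions behaviour). `mask_signal_outside_peaks` zeroes
all signal outside the union of peaks padded by 1 kb, the masking used
to de-noise early-embryo tracks.

## Expression

TMM follows the published algorithm: reference sample by the 75th
count percentile closest to the mean, gene-wise M and A values against
the reference, double trimming (30% on M, 5% on A by rank), and an
inverse-delta-method-variance weighted mean of the surviving M values;
factors are rescaled to geometric mean 1. The implementation matches
edgeR's `calcNormFactors` to < 1e-5 relative error (one test shells out
to Rscript as the independent oracle). Normalized values are counts per
million of the factor-adjusted library size. Scale invariance under
multiplying one library by a constant is approximate (the precision
weights see the raw library size), exactly as in the reference
implementation.

Counts of joined LINE-1 fragments are summed into the joined locus
before normalization. The group-vs-random test averages normalized
expression over the group's features and each stage's replicates
(means over features first, then replicates; the order is immaterial
for balanced designs) and compares against equal-size draws from the
universe, FDR-corrected across stages.

## Synthetic data: what it emulates, and what it does not

The default configuration is a 2 × 10 Mb genome with ~2,000
three-exon genes, ~3,200 background TEs in a mm10-like subfamily mix,
30 planted six-gene clusters (~9% of genes in clusters, emulating the
~10% genome-wide expectation), a 200-gene focal ("minor-wave") set with
30% planted inside clusters (emulating 24% vs 10%) and 17% given a
MERVL within 100 nt of the TSS against a < 1% background rate
(emulating 147/861 = 17% vs < 1%), and 160 full-length 6.5-kb young
LINE-1s placed intergenically: half are split into 2–3 fragments with
genomic gaps of 0–1 nt and consensus gaps of 1–4 nt (exercising the
joining rule), 60% carry a 5' monomer. The designated ATAC stage
(early2C) receives intergenic peaks at the 3' ends of monomer-bearing
LINE-1s; Pol-II peaks sit on monomers with stage membership constructed
so that 87% of 8-cell-bound monomers were bound at the 2-cell stages;
per-locus counts are negative-binomial (dispersion 0.1, two replicates
per stage) with the monomer-bearing LINE-1 group expressed only from
the configured onset stage (late2C). These problem sizes keep the full
simulation under half a second and permutation analyses in seconds
while leaving planted effects many null SDs from the background.

The generator emits coordinates and counts only — no nucleotide
sequence (no in-scope operation reads sequence), no read-level noise,
no mappability structure, and TE placement outside the planted features
is uniform rather than clustered. Passing tests therefore demonstrate
the correctness of the procedures and their statistical calibration
under the generating model, not robustness to multimapping artefacts,
annotation errors or the spatial heterogeneity of a real genome (see
the coordinate-shuffle caveat above for one way such heterogeneity
matters).

## Numerical details

- Degenerate permutation nulls are detected at a relative tolerance of
  1e-9 (float-rounding spread counts as zero SD).
- Fancy-indexed means in the expression test sort indices first, so a
  draw equal to the observed set is bit-identical to it.
- Fractional-overlap thresholds compare `overlap_bp >= min_frac × len`
  exactly on integers (no floating-point boundary drift at 50%).
- TE-assignment and monomer ties break on genomic position;
  defragmentation output is sorted by locus — all outputs are
  deterministic under a fixed seed, and the pipeline manifest records
  SHA-256 checksums to make this checkable.
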