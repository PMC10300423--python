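"""Coordinate model, standard-format I/O and interval algebra.

All coordinates are 0-based half-open internally.  Conversions from
1-based-closed dialects (GTF, RepeatMasker consensus columns as printed
by UCSC-style tables) happen only at the I/O boundary.

Interval sets are plain Python lists of :class:`GenomicInterval` (or
subclasses); performance-sensitive operations convert to per-chromosome
numpy arrays internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tewave")

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered set of chromosomes with lengths (bp).

    Every interval handled by the package must lie within ``[0, length)``
    of one of these chromosomes.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int] = field(compare=False)

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            length = self.chrom_lengths.get(name)
            if length is None or length <= 0:
                raise ValueError(f"chromosome {name!r} lacks a positive length")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), dict(lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def check(self, iv: "GenomicInterval") -> None:
        if iv.chrom not in self.chrom_lengths:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv} exceeds chromosome length "
                f"{self.chrom_lengths[iv.chrom]}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class GeneRecord:
    """A gene with optional functional-domain category and substructure.

    ``category`` is required only for cluster detection.  Exon/UTR
    intervals must lie within the gene span.
    """

    gene_id: str
    span: GenomicInterval
    category: str | None = None
    exons: tuple[GenomicInterval, ...] = ()
    five_utrs: tuple[GenomicInterval, ...] = ()
    three_utrs: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        for sub in (*self.exons, *self.five_utrs, *self.three_utrs):
            if sub.chrom != self.span.chrom or sub.start < self.span.start \
                    or sub.end > self.span.end:
                raise ValueError(
                    f"substructure {sub} outside gene span of {self.gene_id}"
                )


class SignalTrack:
    """Stepwise non-negative genome signal with bedGraph semantics.

    Steps are stored per chromosome as sorted, non-overlapping
    ``(starts, ends, values)`` arrays; uncovered bases have value 0.
    """

    def __init__(self, steps: Iterable[tuple[GenomicInterval, float]] = ()):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in steps:
            if value < 0:
                raise ValueError("signal values must be >= 0")
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, triples in per_chrom.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            values = np.array([t[2] for t in triples], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping steps on {chrom}")
            self._set_chrom(chrom, starts, ends, values)

    def _set_chrom(self, chrom, starts, ends, values):
        self._data[chrom] = (starts, ends, values)
        # prefix sums of value * bp, for O(log n) range integrals
        self._cum[chrom] = np.concatenate(
            [[0.0], np.cumsum(values * (ends - starts))]
        )

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def steps(self) -> list[tuple[GenomicInterval, float]]:
        out = []
        for chrom in self.chroms:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                out.append((GenomicInterval(chrom, int(s), int(e)), float(v)))
        return out

    def integral_at(self, chrom: str, pos) -> np.ndarray:
        """Cumulative signal*bp over ``[0, pos)``, vectorised over ``pos``."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self._data:
            return np.zeros(len(pos))
        starts, ends, _values = self._data[chrom]
        values = _values
        k = np.searchsorted(starts, pos, side="right")
        out = self._cum[chrom][np.maximum(k - 1, 0)].copy()
        has = k > 0
        idx = k[has] - 1
        partial = np.clip(np.minimum(ends[idx], pos[has]) - starts[idx], 0, None)
        out[has] += values[idx] * partial
        return out

    def range_sum(self, iv: GenomicInterval) -> float:
        """Sum of value x bp over the interval (the AUC of a peak)."""
        lo, hi = self.integral_at(iv.chrom, [iv.start, iv.end])
        return float(hi - lo)

    def range_mean(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean signal per bin for consecutive bins given by ``edges``."""
        integ = self.integral_at(chrom, edges)
        widths = np.diff(edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.diff(integ) / widths
        means[widths == 0] = 0.0
        return means


@dataclass(frozen=True)
class TERecord:
    """A RepeatMasker-style TE locus with consensus coordinates.

    Consensus coordinates are kept in the table's 1-based-closed
    convention (``consensus_start < consensus_end``); they are only ever
    compared with each other, never mixed with genomic coordinates.
    ``source_ids`` track the original annotation rows after joining.
    """

    locus: GenomicInterval
    subfamily: str
    family: str = ""
    te_class: str = ""
    consensus_start: int = 0
    consensus_end: int = 0
    source_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.consensus_end and self.consensus_start >= self.consensus_end:
            raise ValueError(
                f"non-positive consensus span for {self.locus.name}"
            )

    @property
    def te_id(self) -> str:
        return self.locus.name or f"{self.locus.chrom}:{self.locus.start}"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

RMSK_COLUMNS = (
    "genoName", "genoStart", "genoEnd", "strand",
    "repName", "repClass", "repFamily", "repStart", "repEnd",
)


def read_chrom_sizes(path) -> GenomeLayout:
    lengths: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected two columns")
        try:
            lengths[parts[0]] = int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return GenomeLayout.from_dict(lengths)


def _filter_layout(records, layout, path):
    if layout is None:
        return records
    kept, dropped = [], 0
    for rec in records:
        iv = rec.locus if isinstance(rec, TERecord) else rec
        iv = iv.span if isinstance(iv, GeneRecord) else iv
        if iv.chrom in layout:
            layout.check(iv)
            kept.append(rec)
        else:
            dropped += 1
    if dropped:
        logger.warning("%s: dropped %d records on unknown chromosomes",
                       path, dropped)
    return kept


def read_bed(path, layout: GenomeLayout | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6 (native 0-based half-open)."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if end <= start:
            raise FormatError(f"{path}:{lineno}: end <= start")
        name = f[3] if len(f) > 3 and f[3] != "." else None
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
        out.append(GenomicInterval(f[0], start, end, strand, name))
    logger.info("%s: read %d BED records", path, len(out))
    return _filter_layout(out, layout, path)


def write_bed(path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{iv.name or '.'}\t0\t{iv.strand}\n")


def read_narrowpeak(path, layout: GenomeLayout | None = None):
    """Read ENCODE narrowPeak (BED6+4); returns (interval, score) pairs."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 10:
            raise FormatError(f"{path}:{lineno}: narrowPeak needs 10 columns")
        try:
            start, end = int(f[1]), int(f[2])
            score = float(f[6])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed narrowPeak") from exc
        if end <= start:
            raise FormatError(f"{path}:{lineno}: end <= start")
        name = f[3] if f[3] != "." else None
        strand = f[5] if f[5] in ("+", "-") else "."
        out.append((GenomicInterval(f[0], start, end, strand, name), score))
    ivs = [iv for iv, _ in out]
    kept = _filter_layout(ivs, layout, path)
    keep_set = set(map(id, kept))
    return [(iv, sc) for iv, sc in out if id(iv) in keep_set]


def write_narrowpeak(path, peaks) -> None:
    """Write (interval, score) pairs as narrowPeak."""
    with open(path, "w") as fh:
        for iv, score in peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                     f"{iv.strand}\t{score:g}\t-1\t-1\t-1\n")


def read_bedgraph(path, layout: GenomeLayout | None = None) -> SignalTrack:
    steps = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        try:
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            value = float(f[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed bedGraph") from exc
        if layout is not None and iv.chrom not in layout:
            continue
        steps.append((iv, value))
    return SignalTrack(steps)


def write_bedgraph(path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for iv, value in track.steps():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


def read_repeatmasker(path, layout: GenomeLayout | None = None) -> list[TERecord]:
    """Read a UCSC rmsk-style tab-separated TE table.

    Genomic coordinates follow the UCSC database convention (0-based
    half-open); ``repStart``/``repEnd`` are 1-based-closed positions on
    the subfamily consensus.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RMSK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.genoEnd <= row.genoStart:
            raise FormatError(f"{path}: row {i}: genoEnd <= genoStart")
        name = getattr(row, "id", None)
        name = str(name) if name is not None else f"te{i}"
        iv = GenomicInterval(row.genoName, int(row.genoStart), int(row.genoEnd),
                             row.strand, name)
        out.append(TERecord(
            locus=iv, subfamily=row.repName, family=row.repFamily,
            te_class=row.repClass,
            consensus_start=int(row.repStart), consensus_end=int(row.repEnd),
            source_ids=(name,),
        ))
    logger.info("%s: read %d TE records", path, len(out))
    return _filter_layout(out, layout, path)


def write_repeatmasker(path, records: Sequence[TERecord]) -> None:
    rows = [{
        "genoName": r.locus.chrom, "genoStart": r.locus.start,
        "genoEnd": r.locus.end, "strand": r.locus.strand,
        "repName": r.subfamily, "repClass": r.te_class,
        "repFamily": r.family, "repStart": r.consensus_start,
        "repEnd": r.consensus_end, "id": r.te_id,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gtf_genes(path, layout: GenomeLayout | None = None) -> list[GeneRecord]:
    """Read gene records (with exon/UTR substructure) from a GTF.

    GTF is 1-based closed; coordinates are converted to 0-based
    half-open on read.  Features recognised: ``gene``, ``exon``,
    ``five_prime_utr``/``5UTR``, ``three_prime_utr``/``3UTR``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )

    def _iv(feat):
        return GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                               feat.strand if feat.strand in "+-" else ".")

    utr5_types = {"five_prime_utr", "five_prime_UTR", "5UTR"}
    utr3_types = {"three_prime_utr", "three_prime_UTR", "3UTR"}
    genes = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("gene_id", [gene.id])[0]
        category = gene.attributes.get("gene_category", [None])[0]
        exons, u5, u3 = [], [], []
        for child in db.children(gene):
            if child.featuretype == "exon":
                exons.append(_iv(child))
            elif child.featuretype in utr5_types:
                u5.append(_iv(child))
            elif child.featuretype in utr3_types:
                u3.append(_iv(child))
        span = replace(_iv(gene), name=gid)
        genes.append(GeneRecord(gid, span, category,
                                tuple(exons), tuple(u5), tuple(u3)))
    logger.info("%s: read %d genes", path, len(genes))
    return _filter_layout(genes, layout, path)


def write_gtf_genes(path, genes: Sequence[GeneRecord]) -> None:
    """Write GeneRecords as GTF (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            if g.category:
                attrs += f' gene_category "{g.category}";'
            base = (g.span.chrom, "tewave")
            fh.write("\t".join([*base, "gene", str(g.span.start + 1),
                                str(g.span.end), ".", g.span.strand, ".",
                                attrs]) + "\n")
            tattrs = attrs + f' transcript_id "{g.gene_id}.t1";'
            fh.write("\t".join([*base, "transcript", str(g.span.start + 1),
                                str(g.span.end), ".", g.span.strand, ".",
                                tattrs]) + "\n")
            for ftype, ivs in (("exon", g.exons),
                               ("five_prime_utr", g.five_utrs),
                               ("three_prime_utr", g.three_utrs)):
                for iv in ivs:
                    fh.write("\t".join([*base, ftype, str(iv.start + 1),
                                        str(iv.end), ".", g.span.strand, ".",
                                        tattrs]) + "\n")


_READERS = {
    "bed": read_bed,
    "gtf-genes": read_gtf_genes,
    "repeatmasker-table": read_repeatmasker,
    "narrowpeak": read_narrowpeak,
    "bedgraph": read_bedgraph,
    "chrom-sizes": lambda path, layout=None: read_chrom_sizes(path),
}


def read_annotation(path, format: str, layout: GenomeLayout | None = None):
    """Dispatch to the reader for the named dialect."""
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown annotation format {format!r}") from None
    return reader(path, layout=layout) if format != "chrom-sizes" \
        else reader(path)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapRecord:
    a_index: int
    b_index: int
    overlap_bp: int
    frac_a: float


def _as_interval(obj) -> GenomicInterval:
    if isinstance(obj, GenomicInterval):
        return obj
    if isinstance(obj, GeneRecord):
        return obj.span
    if isinstance(obj, TERecord):
        return obj.locus
    raise TypeError(f"not an interval carrier: {type(obj)}")


def _chrom_arrays(ivs: Sequence[GenomicInterval]):
    """Per-chromosome (starts, ends, original-index) arrays, start-sorted."""
    per: dict[str, list[int]] = {}
    for i, iv in enumerate(ivs):
        per.setdefault(iv.chrom, []).append(i)
    out = {}
    for chrom, idx in per.items():
        idx = np.array(idx)
        starts = np.array([ivs[i].start for i in idx], dtype=np.int64)
        ends = np.array([ivs[i].end for i in idx], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        out[chrom] = (starts[order], ends[order], idx[order])
    return out


def intersect_fraction(a, b, min_frac_a: float = 0.0,
                       layout: GenomeLayout | None = None
                       ) -> list[OverlapRecord]:
    """All (a, b) overlap pairs with overlap/len(a) >= ``min_frac_a``.

    ``min_frac_a = 0`` reports any positive overlap (bedtools
    ``intersect`` default); ``min_frac_a = 0.5`` mirrors ``-f 0.5``
    applied to the a-file.
    """
    if not 0.0 <= min_frac_a <= 1.0:
        raise ValueError("min_frac_a must be in [0, 1]")
    a_ivs = [_as_interval(x) for x in a]
    b_ivs = [_as_interval(x) for x in b]
    if layout is not None:
        for iv in (*a_ivs, *b_ivs):
            layout.check(iv)
    b_arr = _chrom_arrays(b_ivs)
    out: list[OverlapRecord] = []
    for ai, iv in enumerate(a_ivs):
        if iv.chrom not in b_arr:
            continue
        bs, be, bidx = b_arr[iv.chrom]
        if len(bs) == 0:
            continue
        maxlen = int((be - bs).max())
        lo = np.searchsorted(bs, iv.start - maxlen, side="left")
        hi = np.searchsorted(bs, iv.end, side="left")
        if hi <= lo:
            continue
        ov = np.minimum(be[lo:hi], iv.end) - np.maximum(bs[lo:hi], iv.start)
        keep = ov > 0
        frac = ov / iv.length
        if min_frac_a > 0:
            keep &= frac >= min_frac_a
        for j in np.flatnonzero(keep):
            out.append(OverlapRecord(ai, int(bidx[lo + j]), int(ov[j]),
                                     float(frac[j])))
    return out


def overlaps_any(a, b) -> np.ndarray:
    """Boolean per a-interval: does it overlap any b-interval (>=1 bp)?"""
    hits = np.zeros(len(a), dtype=bool)
    for rec in intersect_fraction(a, b, 0.0):
        hits[rec.a_index] = True
    return hits


def extend_clip(iv: GenomicInterval, left: int, right: int,
                layout: GenomeLayout) -> GenomicInterval:
    """Extend by ``left``/``right`` bp, clipping to chromosome bounds."""
    if left < 0 or right < 0:
        raise ValueError("extensions must be >= 0")
    layout.check(iv)
    return replace(iv, start=max(0, iv.start - left),
                   end=min(layout.length(iv.chrom), iv.end + right))


def merge_intervals(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint, unstranded list."""
    per = _chrom_arrays([_as_interval(x) for x in ivs])
    merged = []
    for chrom in sorted(per):
        starts, ends, _ = per[chrom]
        cur_s, cur_e = None, None
        for s, e in zip(starts, np.maximum.accumulate(ends)):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
    return merged


def derive_rng(seed: int, index: int = 0) -> np.random.Generator:
    """Deterministic per-task generator derived from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))
    )


def shuffle_intervals(ivs: Sequence[GenomicInterval], layout: GenomeLayout,
                      seed, mode: str = "genome-wide"
                      ) -> list[GenomicInterval]:
    """Random uniform re-placement of intervals, preserving lengths.

    ``genome-wide`` places each interval uniformly over all positions in
    the genome where it fits entirely; ``same-chromosome`` keeps each
    interval on its original chromosome.  Identical seeds give identical
    output.  ``seed`` may be an int or a ready ``numpy`` Generator.
    """
    if mode not in ("genome-wide", "same-chromosome"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if not ivs:
        return []
    chroms = list(layout.chrom_names)
    lengths = np.array([layout.length(c) for c in chroms], dtype=np.int64)
    L = np.array([iv.length for iv in ivs], dtype=np.int64)
    if mode == "same-chromosome":
        caps = np.array([layout.length(iv.chrom) for iv in ivs]) - L
        if (caps < 0).any():
            bad = ivs[int(np.argmin(caps))]
            raise ValueError(f"interval {bad} longer than its chromosome")
        starts = rng.integers(0, caps + 1)
        return [replace(iv, start=int(s), end=int(s) + int(l))
                for iv, s, l in zip(ivs, starts, L)]
    # genome-wide: uniform over every position where the interval fits
    slots = np.clip(lengths[:, None] - L[None, :] + 1, 0, None)  # C x n
    total = slots.sum(axis=0)
    if (total == 0).any():
        bad = ivs[int(np.argmin(total))]
        raise ValueError(f"interval {bad} longer than every chromosome")
    u = rng.integers(0, total)
    cum = np.cumsum(slots, axis=0)
    ci = (u[None, :] >= cum).sum(axis=0)
    prefix = np.vstack([np.zeros(len(ivs), dtype=np.int64), cum[:-1]])
    starts = u - prefix[ci, np.arange(len(ivs))]
    return [replace(iv, chrom=chroms[int(c)], start=int(s),
                    end=int(s) + int(l))
            for iv, c, s, l in zip(ivs, ci, starts, L)]


def five_prime_point(gene) -> GenomicInterval:
    """The 1-bp interval at the gene's 5'-most nucleotide (strand-aware)."""
    iv = _as_interval(gene)
    if iv.strand == "+":
        return replace(iv, end=iv.start + 1)
    if iv.strand == "-":
        return replace(iv, start=iv.end - 1)
    raise ValueError(f"unstranded feature {iv} has no 5' end")
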