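"""LINE-1 defragmentation, TE classification, monomer association.

RepeatMasker frequently annotates adjacent portions of one LINE-1
element as separate rows.  Two rows are portions of the same element
when they belong to the same subfamily, sit (nearly) adjacent on the
genome, and represent (nearly) adjacent spans of the subfamily
consensus sequence.  Joining such rows recovers full-length loci, which
matters both for promoter (monomer) assignment and for summing
locus-level read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .core import GenomicInterval, TERecord

logger = logging.getLogger("tewave")

#: Subfamilies whose elements retain an active internal promoter
#: ("young" LINE-1s: A, Gf and Tf).
YOUNG_L1_SUBFAMILIES = frozenset({"L1Md_A", "L1Md_Gf", "L1Md_Tf"})

#: RepeatMasker names pooled as MERVL (internal portion plus MT2 LTRs).
MERVL_SUBFAMILIES = frozenset({
    "MERVL-int", "MERVL_2A-int", "MT2A", "MT2B", "MT2B1", "MT2B2",
    "MT2C_Mm", "MT2_Mm",
})

#: Maximum genomic gap (exclusive, half-open difference) between joinable
#: fragments: "distance on the genome less than 2 nucleotides".
MAX_GENOMIC_GAP = 2
#: Maximum consensus gap (exclusive): "distance on the consensus less
#: than 5 nucleotides".
MAX_CONSENSUS_GAP = 5


@dataclass(frozen=True)
class MonomerRecord:
    """A LINE-1 promoter monomer, optionally tied to a joined LINE-1."""

    locus: GenomicInterval
    monomer_type: str
    associated_line1: str | None = None  # te_id of the joined element

    def __post_init__(self):
        if self.monomer_type not in ("A", "Gf", "Tf"):
            raise ValueError(f"unknown monomer type {self.monomer_type!r}")


@dataclass(frozen=True)
class ClassifyConfig:
    young_l1_names: frozenset = YOUNG_L1_SUBFAMILIES
    mervl_names: frozenset = MERVL_SUBFAMILIES


def classify_te(subfamily: str, te_class: str,
                config: ClassifyConfig = ClassifyConfig()) -> str:
    """Label a TE as young_L1 / old_L1 / MERVL / other.

    LINE-class elements split by subfamily age; MERVL pools the internal
    portion with the MT2 LTR variants regardless of annotated class.
    """
    if subfamily in config.mervl_names:
        return "MERVL"
    if te_class == "LINE" or te_class.startswith("LINE/"):
        return "young_L1" if subfamily in config.young_l1_names else "old_L1"
    return "other"


def _consensus_gap(prev: TERecord, nxt: TERecord) -> int:
    """Consensus-coordinate gap between genomically consecutive portions.

    Portions are ordered 5'->3' in the strand sense: on the minus strand
    the genomically later fragment carries the *smaller* consensus
    coordinates, so the gap is measured the other way round.
    """
    if prev.locus.strand == "-":
        return prev.consensus_start - nxt.consensus_end
    return nxt.consensus_start - prev.consensus_end


def _joinable(prev: TERecord, nxt: TERecord) -> bool:
    if prev.subfamily != nxt.subfamily:
        return False
    if prev.locus.chrom != nxt.locus.chrom \
            or prev.locus.strand != nxt.locus.strand:
        return False
    gap = nxt.locus.start - prev.locus.end
    if gap < 0:
        logger.info("overlapping fragments %s / %s not joined",
                    prev.te_id, nxt.te_id)
        return False
    if gap >= MAX_GENOMIC_GAP:
        return False
    cgap = _consensus_gap(prev, nxt)
    return 0 <= cgap < MAX_CONSENSUS_GAP


def _merge_chain(chain: list[TERecord]) -> TERecord:
    first, last = chain[0], chain[-1]
    locus = replace(first.locus, end=last.locus.end,
                    name="|".join(r.te_id for r in chain))
    return TERecord(
        locus=locus, subfamily=first.subfamily, family=first.family,
        te_class=first.te_class,
        consensus_start=min(r.consensus_start for r in chain),
        consensus_end=max(r.consensus_end for r in chain),
        source_ids=tuple(sid for r in chain for sid in r.source_ids),
    )


def join_line1_fragments(records: Sequence[TERecord]
                         ) -> tuple[list[TERecord], dict[str, str]]:
    """Chain contiguous same-subfamily LINE-1 fragments into single loci.

    Fragments sorted along the genome are joined transitively whenever
    consecutive fragments share subfamily and strand, their genomic gap
    is < 2 nt and their strand-ordered consensus gap is in [0, 5).
    Returns the joined records (non-LINE and unjoinable records pass
    through unchanged) and a map from every original id to the id of the
    record now carrying it.
    """
    groups: dict[tuple[str, str, str], list[TERecord]] = {}
    for rec in records:
        key = (rec.locus.chrom, rec.locus.strand, rec.subfamily)
        groups.setdefault(key, []).append(rec)

    joined: list[TERecord] = []
    chain: list[TERecord] = []
    n_joins = 0

    def flush():
        nonlocal n_joins
        if not chain:
            return
        if len(chain) > 1:
            n_joins += 1
            joined.append(_merge_chain(chain))
        else:
            joined.append(chain[0])
        chain.clear()

    for key in sorted(groups):
        for rec in sorted(groups[key],
                          key=lambda r: (r.locus.start, r.locus.end)):
            if chain and _joinable(chain[-1], rec):
                chain.append(rec)
            else:
                flush()
                chain.append(rec)
        flush()
    joined.sort(key=lambda r: (r.locus.chrom, r.locus.start, r.locus.end))

    join_map = {sid: rec.te_id for rec in joined for sid in rec.source_ids}
    if n_joins:
        logger.info("joined %d fragment chains (%d -> %d records)",
                    n_joins, len(records), len(joined))
    return joined, join_map


def _five_prime_start(l1: TERecord) -> int:
    """Position (bp) of the element's 5'-most base, strand-aware."""
    return l1.locus.start if l1.locus.strand == "+" else l1.locus.end - 1


def associate_monomers(monomers: Sequence[MonomerRecord],
                       line1s: Sequence[TERecord],
                       max_downstream: int = 100,
                       downstream_ref: bool = False
                       ) -> list[MonomerRecord]:
    """Tie each monomer to the nearest same-strand LINE-1 5' start.

    A monomer qualifies when it overlaps the LINE-1 5'-start base or
    begins no more than ``max_downstream`` bp 3'-ward of it (strand
    sense by default; ``downstream_ref`` switches to plain
    reference-coordinate downstream, mirroring ``bedtools closest -D
    ref``).  Nearest start wins; ties break on smaller genomic start.
    """
    by_strand: dict[str, list[TERecord]] = {"+": [], "-": []}
    for l1 in line1s:
        if l1.locus.strand in by_strand:
            by_strand[l1.locus.strand].append(l1)

    out = []
    for mono in monomers:
        candidates = by_strand.get(mono.locus.strand, [])
        best: tuple[int, int, TERecord] | None = None
        for l1 in candidates:
            if l1.locus.chrom != mono.locus.chrom:
                continue
            s = _five_prime_start(l1)
            overlaps = mono.locus.start <= s < mono.locus.end
            if mono.locus.strand == "+" or downstream_ref:
                d = mono.locus.start - s
            else:
                d = s - (mono.locus.end - 1)
            ok = overlaps or (0 < d <= max_downstream)
            if not ok:
                continue
            dist = 0 if overlaps else d
            key = (abs(dist), l1.locus.start)
            if best is None or key < (best[0], best[1]):
                best = (key[0], key[1], l1)
        if best is not None:
            out.append(replace(mono, associated_line1=best[2].te_id))
        else:
            out.append(replace(mono, associated_line1=None))
    return out
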