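"""Endosperm cis-element scanning of promoter sequences.

Two elements mark endosperm expression in cereal and oilseed promoters: the
skn-1 motif (core GTCAT) and the GCN4 motif (core TGAGTCA).  Promoters are
scanned for exact core occurrences on both strands (reverse-strand hits are
reported in forward coordinates); overlapping occurrences all count, and N
never matches.  A promoter is flagged endosperm-competent when it carries at
least one occurrence of either element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import ValidationError
from .seq_io import PromoterRecord

SKN1 = "skn-1"
GCN4 = "GCN4"


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    core: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "core", self.core.upper())
        if len(self.core) < 4:
            raise ValidationError(f"motif {self.name!r}: core shorter than 4 bases")
        if set(self.core) - set("ACGT"):
            raise ValidationError(f"motif {self.name!r}: core must be A/C/G/T only")


DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition(SKN1, "GTCAT"),
    MotifDefinition(GCN4, "TGAGTCA"),
)

#: Motifs whose presence flags endosperm expression competence.
ENDOSPERM_MOTIFS = (SKN1, GCN4)


@dataclass(frozen=True)
class MotifHit:
    """One exact core occurrence, BED-style 0-based half-open forward coordinates."""

    gene_id: str
    motif_name: str
    start: int
    end: int
    strand: str
    offset_from_atg: int  # start - promoter_length; -1 = base immediately upstream

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValidationError("require 0 <= start < end")


@dataclass(frozen=True)
class PromoterAnnotation:
    gene_id: str
    counts: Mapping[str, int]
    endosperm_flag: bool


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _occurrences(seq: str, core: str) -> list[int]:
    """All (possibly overlapping) exact match start offsets of core in seq."""
    k = len(core)
    return [i for i in range(len(seq) - k + 1) if seq[i : i + k] == core]


def scan_promoter(
    promoter: PromoterRecord,
    motifs: Sequence[MotifDefinition] = DEFAULT_MOTIFS,
    strands: str = "both",
) -> tuple[list[MotifHit], PromoterAnnotation]:
    """Report every exact motif-core occurrence in one promoter.

    Reverse-strand occurrences are found by matching the reverse complement of
    the core against the forward sequence, so their coordinates are already on
    the forward strand.
    """
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    seq = promoter.sequence
    if not seq:
        raise ValidationError(f"promoter {promoter.gene_id!r} is empty")
    length = len(seq)
    hits: list[MotifHit] = []
    counts: dict[str, int] = {m.name: 0 for m in motifs}
    for motif in motifs:
        k = len(motif.core)
        for start in _occurrences(seq, motif.core):
            hits.append(
                MotifHit(promoter.gene_id, motif.name, start, start + k, "+", start - length)
            )
            counts[motif.name] += 1
        if strands == "both":
            rc = revcomp(motif.core)
            for start in _occurrences(seq, rc):
                if rc == motif.core and any(
                    h.start == start and h.motif_name == motif.name for h in hits
                ):
                    continue  # palindromic core: one occurrence, not two
                hits.append(
                    MotifHit(promoter.gene_id, motif.name, start, start + k, "-", start - length)
                )
                counts[motif.name] += 1
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    flag = any(counts.get(name, 0) >= 1 for name in ENDOSPERM_MOTIFS)
    annotation = PromoterAnnotation(promoter.gene_id, counts, flag)
    return hits, annotation


def annotate_family(
    promoters: Iterable[PromoterRecord],
    motifs: Sequence[MotifDefinition] = DEFAULT_MOTIFS,
    strands: str = "both",
) -> tuple[list[MotifHit], list[PromoterAnnotation]]:
    """Scan a promoter collection; gene ids must be unique."""
    promoters = list(promoters)
    ids = [p.gene_id for p in promoters]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate promoter gene id(s): {dupes}")
    all_hits: list[MotifHit] = []
    annotations: list[PromoterAnnotation] = []
    for promoter in promoters:
        hits, annotation = scan_promoter(promoter, motifs, strands)
        all_hits.extend(hits)
        annotations.append(annotation)
    return all_hits, annotations


def hits_to_bed_rows(hits: Iterable[MotifHit]) -> list[tuple]:
    """BED6 rows (chrom=gene, start, end, name=motif, score=0, strand) + ATG offset."""
    return [
        (h.gene_id, h.start, h.end, h.motif_name, 0, h.strand, h.offset_from_atg)
        for h in hits
    ]
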