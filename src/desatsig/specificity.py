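"""Rule-based substrate-specificity classification of pocket signatures.

The family splits on a simple archetype rule: a signature whose eight residues
all fall within the omega-9 archetype's allowed sets is called ``omega9``
(predicted 18:0-ACP specific); any divergence makes it an ``omega7_candidate``
(predicted 16:0-ACP specific); a signature with a gapped pocket column is
``unresolved``.  A nearest-reference rule was rejected deliberately: a true
omega-7 enzyme divergent at four positions can still sit closest to the
archetype, whereas the published grouping is exactly "identical to the
archetype or not".

Positionwise identities against each reference-panel signature are reported
alongside the call so divergent-but-equivalent enzymes (which can share as few
as five of eight residues) remain visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ValidationError
from .pocket_map import GAP, POCKET_POSITIONS, PocketSignature
from .resources import load_archetype_sets, load_pocket_table

OMEGA9 = "omega9"
OMEGA7 = "omega7_candidate"
UNRESOLVED = "unresolved"
CLASSES = (OMEGA9, OMEGA7, UNRESOLVED)


@dataclass(frozen=True)
class ArchetypeProfile:
    """Allowed residue sets of the omega-9 archetype, ascending position order."""

    allowed: tuple[frozenset, ...]
    positions: tuple[int, ...] = POCKET_POSITIONS

    def __post_init__(self) -> None:
        if len(self.allowed) != len(self.positions):
            raise ValidationError("one allowed set per pocket position required")
        for s in self.allowed:
            if not s:
                raise ValidationError("allowed sets must be non-empty")

    @classmethod
    def default(cls) -> "ArchetypeProfile":
        positions, allowed = load_archetype_sets()
        return cls(allowed=allowed, positions=positions)

    @classmethod
    def strict(cls) -> "ArchetypeProfile":
        """Strict identity to the archetype residues (no L/I tolerance)."""
        positions, allowed = load_archetype_sets()
        strict_sets = tuple(frozenset([sorted(s)[-1]]) if s == frozenset("IL") else s
                            for s in allowed)
        return cls(allowed=strict_sets, positions=positions)

    @classmethod
    def from_json(cls, path) -> "ArchetypeProfile":
        with open(path) as handle:
            raw = json.load(handle)
        return cls(
            allowed=tuple(frozenset(s) for s in raw["allowed"]),
            positions=tuple(raw["positions"]),
        )


@dataclass(frozen=True)
class ReferencePanel:
    """Complete pocket signatures and class labels of the reference enzymes."""

    entries: Mapping[str, PocketSignature]
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        for ref_id, sig in self.entries.items():
            if not sig.is_complete:
                raise ValidationError(f"panel signature {ref_id!r} contains a gap")
            if ref_id not in self.labels:
                raise ValidationError(f"panel entry {ref_id!r} has no class label")

    @classmethod
    def default(cls) -> "ReferencePanel":
        table = load_pocket_table()
        entries = {}
        labels = {}
        for ref_id, entry in table["references"].items():
            entries[ref_id] = PocketSignature(
                protein_id=ref_id,
                residues=tuple(entry["residues"]),
                query_positions=tuple(entry["printed_indices"]),
            )
            labels[ref_id] = OMEGA9 if entry["class"] == "omega9" else OMEGA7
        return cls(entries=entries, labels=labels)


def signature_identity(a: PocketSignature, b: PocketSignature) -> float:
    """Fraction of the eight positions with identical residues (gaps never match)."""
    matches = sum(
        1
        for ra, rb in zip(a.residues, b.residues)
        if ra != GAP and ra == rb
    )
    return matches / len(a.residues)


@dataclass(frozen=True)
class SpecificityCall:
    protein_id: str
    call: str
    archetype_matches: int
    per_reference_identity: Mapping[str, float] = field(default_factory=dict)


def classify(
    signature: PocketSignature,
    archetype: ArchetypeProfile | None = None,
    panel: ReferencePanel | None = None,
) -> SpecificityCall:
    """Classify one pocket signature.

    ``omega9`` iff every residue lies in the archetype's allowed set for its
    position; ``unresolved`` iff any position is gapped; ``omega7_candidate``
    otherwise.
    """
    archetype = archetype or ArchetypeProfile.default()
    panel = panel or ReferencePanel.default()
    if len(signature.residues) != len(archetype.allowed):
        raise ValidationError(
            f"signature {signature.protein_id!r} has {len(signature.residues)} "
            f"residues; expected {len(archetype.allowed)}"
        )
    matches = sum(
        1 for res, allowed in zip(signature.residues, archetype.allowed) if res in allowed
    )
    if GAP in signature.residues:
        call = UNRESOLVED
    elif matches == len(archetype.allowed):
        call = OMEGA9
    else:
        call = OMEGA7
    identities = {
        ref_id: signature_identity(signature, ref_sig)
        for ref_id, ref_sig in panel.entries.items()
    }
    return SpecificityCall(
        protein_id=signature.protein_id,
        call=call,
        archetype_matches=matches,
        per_reference_identity=identities,
    )


@dataclass(frozen=True)
class FamilySummary:
    counts: Mapping[str, int]
    members: Mapping[str, tuple[str, ...]]

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "members": {k: list(v) for k, v in self.members.items()},
        }


def group_family(calls: Iterable[SpecificityCall]) -> FamilySummary:
    """Partition calls into the three classes with sorted member lists."""
    calls = list(calls)
    if not calls:
        raise ValidationError("no calls to summarize")
    ids = [c.protein_id for c in calls]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate protein id(s) in calls: {dupes}")
    members = {cls: tuple(sorted(c.protein_id for c in calls if c.call == cls))
               for cls in CLASSES}
    counts = {cls: len(members[cls]) for cls in CLASSES}
    return FamilySummary(counts=counts, members=members)


def table_signatures() -> list[PocketSignature]:
    """The 17 family signatures from the packaged pocket table (print transcription)."""
    table = load_pocket_table()
    sigs = []
    for gene_id, entry in table["family"].items():
        sigs.append(
            PocketSignature(
                protein_id=gene_id,
                residues=tuple(entry["residues"]),
                query_positions=tuple(entry["printed_indices"]),
            )
        )
    return sigs
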