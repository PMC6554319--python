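"""Loaders for the packaged fixtures.

The pocket-signature table and the archetype profile are transcriptions of the
published residue data.  The protein FASTA files are *synthetic* scaffold
sequences (the study deposited no sequence records): a fixed pseudo-random
archetype scaffold carries each entry's verbatim pocket letters at coordinates
consistent with its printed numbering offset, so alignment-based extraction
reproduces the published signatures end-to-end.
"""

from __future__ import annotations

import json
from collections import Counter
from functools import lru_cache
from importlib import resources as importlib_resources

from .seq_io import ProteinRecord, read_fasta


def _data_path(name: str):
    return importlib_resources.files("desatsig.data").joinpath(name)


@lru_cache(maxsize=None)
def load_pocket_table() -> dict:
    """The published eight-residue pocket table (references + 17 family members)."""
    with _data_path("pocket_signatures.json").open() as handle:
        return json.load(handle)


@lru_cache(maxsize=None)
def load_archetype_sets() -> tuple[tuple[int, ...], tuple[frozenset, ...]]:
    """Positions and allowed residue sets of the omega-9 archetype profile."""
    with _data_path("archetype.json").open() as handle:
        raw = json.load(handle)
    return tuple(raw["positions"]), tuple(frozenset(s) for s in raw["allowed"])


@lru_cache(maxsize=None)
def load_fame_masses() -> dict[str, float]:
    """Methyl-ester molar masses (g/mol) for the packaged species vocabulary."""
    with _data_path("fame_methyl_ester_masses.json").open() as handle:
        return dict(json.load(handle)["masses"])


@lru_cache(maxsize=None)
def load_reference_panel_records() -> list[ProteinRecord]:
    """Synthetic sequences of the five reference enzymes (RcSAD1 first)."""
    with importlib_resources.as_file(_data_path("reference_panel.synthetic.faa")) as p:
        return read_fasta(p, alphabet="protein")


@lru_cache(maxsize=None)
def load_family_records() -> list[ProteinRecord]:
    """Synthetic sequences of the 17 cotton family members."""
    with importlib_resources.as_file(_data_path("ghsad_family.synthetic.faa")) as p:
        return read_fasta(p, alphabet="protein")


def get_rcsad1() -> ProteinRecord:
    """The packaged archetype reference sequence."""
    rec = load_reference_panel_records()[0]
    assert rec.id == "RcSAD1"
    return rec


@lru_cache(maxsize=None)
def load_domain_block() -> dict:
    """Ungapped conserved block of the reference panel plus the frozen threshold."""
    with _data_path("domain_block.synthetic.json").open() as handle:
        return json.load(handle)


def numbering_offset(entry: dict, canonical_positions) -> int:
    """Most common difference between printed indices and reference numbering.

    A few printed indices are inconsistent within their own column; the modal
    offset recovers the column's numbering frame.
    """
    diffs = [p - c for p, c in zip(entry["printed_indices"], canonical_positions)]
    return Counter(diffs).most_common(1)[0][0]
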