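"""Sequence and table I/O shared by every pipeline stage.

Protein records hold the desaturase family members and the reference panel;
promoter records hold the 2-kb upstream regions scanned for endosperm
cis-elements.  FASTA parsing is delegated to Biopython and wrapped with the
validation the downstream stages rely on (upper-cased sequences, restricted
alphabets, unique identifiers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaParseError, SchemaError, ValidationError

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

#: Nominal upstream-region length; longer promoters draw a warning, not an error.
PROMOTER_NOMINAL_LENGTH = 2000


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence (20 standard letters plus X)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise ValidationError("protein record with empty id")
        if not self.sequence:
            raise ValidationError(f"protein record {self.id!r} has empty sequence")
        _check_alphabet(self.id, self.sequence, PROTEIN_ALPHABET, "protein")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PromoterRecord:
    """Upstream nucleotide sequence of one gene, 3' end abutting the ATG."""

    gene_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.gene_id:
            raise ValidationError("promoter record with empty gene id")
        if not self.sequence:
            raise ValidationError(f"promoter {self.gene_id!r} has empty sequence")
        _check_alphabet(self.gene_id, self.sequence, DNA_ALPHABET, "promoter")
        if len(self.sequence) > PROMOTER_NOMINAL_LENGTH:
            warnings.warn(
                f"promoter {self.gene_id!r} is {len(self.sequence)} bp, longer than "
                f"the nominal {PROMOTER_NOMINAL_LENGTH} bp upstream region",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _check_alphabet(rec_id: str, seq: str, alphabet: frozenset, kind: str) -> None:
    for pos, letter in enumerate(seq, start=1):
        if letter not in alphabet:
            raise ValidationError(
                f"{kind} record {rec_id!r}: illegal character {letter!r} at position {pos}"
            )


def read_fasta(path: str | Path, alphabet: str = "protein"):
    """Read a multi-record FASTA file.

    Parameters
    ----------
    path
        FASTA file.
    alphabet
        ``"protein"`` yields :class:`ProteinRecord`, ``"dna"`` yields
        :class:`PromoterRecord`.

    Returns one record per entry, order preserved.  Duplicate identifiers,
    empty sequences and out-of-alphabet letters raise.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"alphabet must be 'protein' or 'dna', got {alphabet!r}")
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    records = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed entries this way
        raise FastaParseError(f"{path}: {exc}") from exc
    if not parsed:
        raise FastaParseError(f"{path}: no FASTA records found")
    for i, rec in enumerate(parsed, start=1):
        if not rec.id:
            raise FastaParseError(f"{path}: entry {i} has an empty header")
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"{path}: entry {i} ({rec.id!r}) has an empty sequence")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        if alphabet == "protein":
            records.append(ProteinRecord(rec.id, seq, desc))
        else:
            records.append(PromoterRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[ProteinRecord | PromoterRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrap), ids and sequences verbatim."""
    seqrecords = []
    for rec in records:
        rec_id = rec.id if isinstance(rec, ProteinRecord) else rec.gene_id
        seqrecords.append(SeqRecord(Seq(rec.sequence), id=rec_id, description=rec.description))
    with open(path, "w") as handle:
        SeqIO.write(seqrecords, handle, "fasta")


#: Required column names for the two delimited-table kinds.
CQ_COLUMNS = ("gene", "sample", "replicate", "cq")
PEAK_COLUMNS = ("sample", "species", "area")


def sniff_delimiter(path: str | Path) -> str:
    """Tab if the header line contains a tab, otherwise comma."""
    with open(path) as handle:
        header = handle.readline()
    return "\t" if "\t" in header else ","


def read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a delimited table, auto-detecting tab vs comma from the header.

    Raises :class:`SchemaError` listing expected vs found columns when a
    required column is missing.  Missing values are kept as NaN and flagged
    with a warning so no row is silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sniff_delimiter(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {list(required)}, found {list(df.columns)}"
        )
    n_na = int(df[list(required)].isna().sum().sum())
    if n_na:
        warnings.warn(f"{path}: {n_na} missing value(s) in required columns", stacklevel=2)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV without the index."""
    df.to_csv(path, sep="\t", index=False)
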