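"""Family-membership triage by position-specific scoring.

Before pocket mapping, each input protein is screened for the soluble
desaturase core: a position-specific scoring matrix (PSSM) built from an
ungapped conserved block of the five reference enzymes is slid along the
protein and the best window score is compared against a frozen threshold.
This is deliberately a PSSM, not a profile HMM — the gate only needs
desk-scale family triage, and the alignment stage downstream tolerates indels.

Column scores are log2-odds of the observed residue frequency (with a
pseudocount) against the uniform 1/20 background, so scores are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .resources import load_domain_block
from .seq_io import PROTEIN_ALPHABET, ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)


@dataclass(frozen=True)
class DomainProfile:
    """PSSM over an ungapped block; ``scores`` is (length, 20) in bits."""

    name: str
    scores: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != N_AA:
            raise ValidationError("profile scores must be (length, 20)")
        if self.scores.shape[0] < 2:
            raise ValidationError("profile must span at least 2 columns")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("profile scores must be finite")

    def __len__(self) -> int:
        return int(self.scores.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.scores, axis=1))

    @property
    def max_score(self) -> float:
        return float(np.max(self.scores, axis=1).sum())


@dataclass(frozen=True)
class DomainCall:
    protein_id: str
    best_score: float
    best_offset: int
    positive: bool


def build_profile(
    block: Sequence[str],
    pseudocount: float = 0.5,
    name: str = "FA_desaturase_2",
    threshold: float | None = None,
) -> DomainProfile:
    """Build a log-odds PSSM from equal-length ungapped segments.

    ``score[j, a] = log2( (n_aj + p) / (N + 20 p) / (1/20) )`` with pseudocount
    ``p > 0``.  Default threshold is half the consensus (maximum attainable)
    score, which cleanly separates the packaged references from shuffles.
    """
    if len(block) < 2:
        raise ValidationError("need at least 2 segments to build a profile")
    length = len(block[0])
    if any(len(seg) != length for seg in block):
        raise ValidationError(
            f"unequal segment lengths: {sorted({len(s) for s in block})}"
        )
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0 (log of zero frequency)")
    counts = np.zeros((length, N_AA), dtype=float)
    for seg in block:
        for j, aa in enumerate(seg.upper()):
            if aa not in _AA_INDEX:
                raise ValidationError(f"segment residue {aa!r} not a standard amino acid")
            counts[j, _AA_INDEX[aa]] += 1.0
    n = float(len(block))
    freqs = (counts + pseudocount) / (n + N_AA * pseudocount)
    scores = np.log2(freqs / (1.0 / N_AA))
    profile = DomainProfile(name=name, scores=scores, threshold=0.0)
    if threshold is None:
        threshold = 0.5 * profile.max_score
    return DomainProfile(name=name, scores=scores, threshold=float(threshold))


def default_profile() -> DomainProfile:
    """The packaged profile: reference-panel block with its frozen threshold."""
    raw = load_domain_block()
    profile = build_profile(
        raw["segments"],
        pseudocount=raw["pseudocount"],
        name=raw["name"],
        threshold=raw["threshold"],
    )
    if len(profile) < 20:
        raise ValidationError("packaged domain block must span at least 20 columns")
    return profile


def scan_protein(protein: ProteinRecord, profile: DomainProfile | None = None) -> DomainCall:
    """Best-window PSSM scan; ties resolved to the smallest offset.

    Residues outside the 20 standard letters (X) contribute the column's mean
    score, a neutral treatment for ambiguity codes.
    """
    profile = profile or default_profile()
    w = len(profile)
    seq = protein.sequence
    if len(seq) < w:
        raise ValidationError(
            f"protein {protein.id!r} length {len(seq)} shorter than profile length {w}"
        )
    col_mean = profile.scores.mean(axis=1)
    encoded = np.array([_AA_INDEX.get(a, -1) for a in seq])
    known = encoded >= 0
    n_windows = len(seq) - w + 1
    window_scores = np.zeros(n_windows)
    for j in range(w):
        col = profile.scores[j]
        contrib = np.where(known, col[np.clip(encoded, 0, None)], col_mean[j])
        window_scores += contrib[j : j + n_windows]
    best_offset = int(np.argmax(window_scores))  # argmax returns first = smallest offset
    best_score = float(window_scores[best_offset])
    return DomainCall(
        protein_id=protein.id,
        best_score=best_score,
        best_offset=best_offset,
        positive=best_score >= profile.threshold,
    )


def scan_family(
    proteins: Sequence[ProteinRecord], profile: DomainProfile | None = None
) -> list[DomainCall]:
    profile = profile or default_profile()
    return [scan_protein(p, profile) for p in proteins]
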