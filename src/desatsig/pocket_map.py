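"""Reference-anchored pocket-residue extraction.

Each candidate desaturase is globally aligned to the RcSAD1 archetype and the
eight substrate-channel positions (M114, L115, T117, L118, P179, T181, G188,
F189 in RcSAD1 numbering) are transferred through the alignment into query
coordinates.  The ordered eight query residues form the protein's *pocket
signature*, the sole input of the substrate-specificity classifier.

The aligner is a Gotoh affine-gap Needleman-Wunsch with BLOSUM62 (gap open 10,
extend 1; a gap of length L costs ``open + (L-1)*extend``).  Traceback ties are
broken deterministically, diagonal over up over left, so signatures are
reproducible across runs.  Full-length family homologs make global alignment
the natural numbering-transfer choice; indels relative to the archetype are
absorbed as gaps, and a gap falling on a pocket column is propagated as a GAP
marker rather than an invented residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .seq_io import ProteinRecord

GAP = "-"

#: 1-based RcSAD1 indices of the eight substrate-channel residues.
POCKET_POSITIONS = (114, 115, 117, 118, 179, 181, 188, 189)
#: RcSAD1 residues at those indices.
POCKET_RESIDUES = "MLTLPTGF"

_NEG = np.int64(-(2**40))


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open < self.gap_extend or self.gap_extend < 0:
            raise ValidationError("require gap_open >= gap_extend >= 0")

    def as_dict(self) -> dict:
        return {
            "matrix": self.matrix_name,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
        }


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    index = {aa: i for i, aa in enumerate(alphabet)}
    arr = np.asarray(mat, dtype=np.int64)
    return index, arr


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    try:
        return np.array([index[a] for a in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValidationError(f"residue {exc.args[0]!r} not in substitution matrix") from exc


@dataclass(frozen=True)
class ReferencePocket:
    """The archetype's pocket positions and their canonical residues."""

    reference_id: str = "RcSAD1"
    positions: tuple[int, ...] = POCKET_POSITIONS
    canonical_residues: str = POCKET_RESIDUES

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValidationError("pocket positions must be strictly increasing")
        if len(self.canonical_residues) != len(self.positions):
            raise ValidationError("one canonical residue per pocket position required")

    def check_reference(self, reference: ProteinRecord) -> None:
        """Assert the canonical residues occur at the stated reference indices."""
        for pos, res in zip(self.positions, self.canonical_residues):
            if pos > len(reference) or reference.sequence[pos - 1] != res:
                raise ValidationError(
                    f"reference {reference.id!r} does not carry {res} at position {pos}"
                )


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal global alignment of a query against the reference.

    ``column_map`` sends every 1-based reference position to the matching
    1-based query position, or ``None`` where the query has a gap.
    """

    query_id: str
    reference_id: str
    aligned_query: str
    aligned_reference: str
    score: int
    column_map: dict[int, int | None] = field(repr=False)

    @property
    def query_sequence(self) -> str:
        return self.aligned_query.replace(GAP, "")

    @property
    def reference_sequence(self) -> str:
        return self.aligned_reference.replace(GAP, "")


@dataclass(frozen=True)
class PocketSignature:
    """Ordered pocket residues of one protein, ascending reference position."""

    protein_id: str
    residues: tuple[str, ...]
    query_positions: tuple[int | None, ...]

    @property
    def is_complete(self) -> bool:
        return GAP not in self.residues

    def as_string(self) -> str:
        return "".join(self.residues)


def global_align(query: str, reference: str, scoring: ScoringScheme | None = None):
    """Optimal global (Needleman-Wunsch) alignment with affine gaps.

    Returns ``(score, aligned_query, aligned_reference)``.  Dynamic program is
    the three-state Gotoh recursion, vectorized row-wise; the left-gap state is
    folded into a running maximum so each row costs O(m) numpy work.
    """
    scoring = scoring or ScoringScheme()
    if not query or not reference:
        raise ValidationError("cannot align empty sequences")
    index, smat = _load_matrix(scoring.matrix_name)
    q = _encode(query, index)
    r = _encode(reference, index)
    n, m = len(q), len(r)
    go, ge = np.int64(scoring.gap_open), np.int64(scoring.gap_extend)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in reference (consumes query, "up")
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in query (consumes reference, "left")
    M[0, 0] = 0
    j_idx = np.arange(1, m + 1, dtype=np.int64)
    Y[0, 1:] = -(go + (j_idx - 1) * ge)
    i_idx = np.arange(1, n + 1, dtype=np.int64)
    X[1:, 0] = -(go + (i_idx - 1) * ge)

    ext_ramp = np.arange(m + 1, dtype=np.int64) * ge
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + smat[q[i - 1], r]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - go, X[i - 1, 1:] - ge
        )
        # Y[i, j] = max_{k<j} ( max(M,X)[i,k] - open - (j-1-k) * extend )
        opener = np.maximum(M[i], X[i]) - go + ext_ramp
        running = np.maximum.accumulate(opener[:-1])
        Y[i, 1:] = running - ext_ramp[1:] + ge

    aligned_q, aligned_r = _traceback(M, X, Y, q, r, smat, go, ge, query, reference)
    score = int(max(M[n, m], X[n, m], Y[n, m]))
    return score, aligned_q, aligned_r


def _traceback(M, X, Y, q, r, smat, go, ge, query, reference):
    n, m = len(q), len(r)
    i, j = n, m
    state = _best_state(M[i, j], X[i, j], Y[i, j])
    out_q: list[str] = []
    out_r: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_q.append(query[i - 1])
            out_r.append(reference[j - 1])
            target = M[i, j] - smat[q[i - 1], r[j - 1]]
            i, j = i - 1, j - 1
            state = _best_state(
                M[i, j] if M[i, j] == target else _NEG,
                X[i, j] if X[i, j] == target else _NEG,
                Y[i, j] if Y[i, j] == target else _NEG,
            )
        elif state == "X":
            out_q.append(query[i - 1])
            out_r.append(GAP)
            val = X[i, j]
            i -= 1
            if M[i, j] - go == val:
                state = "M"
            elif X[i, j] - ge == val:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            out_q.append(GAP)
            out_r.append(reference[j - 1])
            val = Y[i, j]
            j -= 1
            if M[i, j] - go == val:
                state = "M"
            elif X[i, j] - go == val:
                state = "X"
            else:
                state = "Y"
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return "".join(reversed(out_q)), "".join(reversed(out_r))


def _best_state(m_val, x_val, y_val) -> str:
    # Deterministic tie-break: diagonal > up > left.
    best = max(m_val, x_val, y_val)
    if m_val == best:
        return "M"
    if x_val == best:
        return "X"
    return "Y"


def align_to_reference(
    query: ProteinRecord,
    reference: ProteinRecord,
    scoring: ScoringScheme | None = None,
) -> AlignmentResult:
    """Globally align ``query`` to ``reference`` and build the column map."""
    score, aq, ar = global_align(query.sequence, reference.sequence, scoring)
    column_map: dict[int, int | None] = {}
    qpos = rpos = 0
    for cq, cr in zip(aq, ar):
        if cq != GAP:
            qpos += 1
        if cr != GAP:
            rpos += 1
            column_map[rpos] = qpos if cq != GAP else None
    return AlignmentResult(
        query_id=query.id,
        reference_id=reference.id,
        aligned_query=aq,
        aligned_reference=ar,
        score=score,
        column_map=column_map,
    )


def extract_signature(alignment: AlignmentResult, pocket: ReferencePocket | None = None) -> PocketSignature:
    """Read the eight pocket residues of the query off the alignment columns."""
    pocket = pocket or ReferencePocket()
    if alignment.reference_id != pocket.reference_id:
        raise ValidationError(
            f"alignment reference {alignment.reference_id!r} does not match "
            f"pocket reference {pocket.reference_id!r}"
        )
    query_seq = alignment.query_sequence
    residues: list[str] = []
    positions: list[int | None] = []
    for ref_pos in pocket.positions:
        if ref_pos not in alignment.column_map:
            raise ValidationError(
                f"reference position {ref_pos} absent from alignment of {alignment.query_id!r}"
            )
        qpos = alignment.column_map[ref_pos]
        if qpos is None:
            residues.append(GAP)
            positions.append(None)
        else:
            residues.append(query_seq[qpos - 1])
            positions.append(qpos)
    return PocketSignature(alignment.query_id, tuple(residues), tuple(positions))
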