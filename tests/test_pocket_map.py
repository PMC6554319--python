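"""Alignment engine and pocket-signature extraction.

The affine-gap global aligner is checked against two independent oracles:
exhaustive enumeration of all alignments for short peptides, and biotite's
``align_optimal`` for realistic lengths.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from desatsig.errors import ValidationError
from desatsig.pocket_map import (
    GAP,
    POCKET_POSITIONS,
    POCKET_RESIDUES,
    ReferencePocket,
    ScoringScheme,
    _load_matrix,
    align_to_reference,
    extract_signature,
    global_align,
)
from desatsig.seq_io import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
SCHEME = ScoringScheme()
_INDEX, _SMAT = _load_matrix("BLOSUM62")


def brute_force_score(a: str, b: str, go: int = 10, ge: int = 1) -> int:
    """Maximum alignment score by full enumeration (independent of the DP)."""
    best = -(10**9)

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _SMAT[_INDEX[a[i]], _INDEX[b[j]]], "M")
        if i < len(a):
            rec(i + 1, j, score - (ge if last == "X" else go), "X")
        if j < len(b):
            rec(i, j + 1, score - (ge if last == "Y" else go), "Y")

    rec(0, 0, 0, None)
    return best


def test_identity_alignment_has_identity_column_map():
    aln = align_to_reference(ProteinRecord("q", "MKV"), ProteinRecord("r", "MKV"))
    assert GAP not in aln.aligned_query + aln.aligned_reference
    assert aln.column_map == {1: 1, 2: 2, 3: 3}


def test_single_insertion_shifts_mapping():
    aln = align_to_reference(ProteinRecord("q", "MAKV"), ProteinRecord("r", "MKV"))
    assert aln.column_map[2] == 3
    assert brute_force_score("MAKV", "MKV") == aln.score


def test_alignment_score_equals_bruteforce_on_random_short_peptides():
    rng = np.random.default_rng(4242)
    for _ in range(120):
        a = "".join(rng.choice(list(AA), rng.integers(1, 7)))
        b = "".join(rng.choice(list(AA), rng.integers(1, 7)))
        score, aq, ar = global_align(a, b, SCHEME)
        assert aq.replace(GAP, "") == a and ar.replace(GAP, "") == b
        assert score == brute_force_score(a, b)


@given(
    st.text(alphabet=AA, min_size=1, max_size=5),
    st.text(alphabet=AA, min_size=1, max_size=5),
)
def test_alignment_score_equals_bruteforce_property(a, b):
    score, _, _ = global_align(a, b, SCHEME)
    assert score == brute_force_score(a, b)


def test_alignment_score_matches_biotite_on_long_sequences():
    biotite_seq = pytest.importorskip("biotite.sequence")
    biotite_align = pytest.importorskip("biotite.sequence.align")
    matrix = biotite_align.SubstitutionMatrix.std_protein_matrix()
    rng = np.random.default_rng(7)
    for _ in range(8):
        a = "".join(rng.choice(list(AA), rng.integers(80, 250)))
        b = "".join(rng.choice(list(AA), rng.integers(80, 250)))
        score, _, _ = global_align(a, b, SCHEME)
        ref = biotite_align.align_optimal(
            biotite_seq.ProteinSequence(a),
            biotite_seq.ProteinSequence(b),
            matrix,
            gap_penalty=(-10, -1),
            terminal_penalty=True,
            max_number=1,
        )[0]
        assert score == ref.score


def test_self_alignment_is_gapless_and_maximal(rcsad1):
    aln = align_to_reference(rcsad1, rcsad1)
    assert GAP not in aln.aligned_query
    diag = sum(_SMAT[_INDEX[a], _INDEX[a]] for a in rcsad1.sequence)
    assert aln.score == diag
    assert aln.column_map == {i: i for i in range(1, len(rcsad1) + 1)}


def test_column_map_is_monotone(rcsad1):
    rng = np.random.default_rng(13)
    seq = list(rcsad1.sequence)
    del seq[50:60]
    seq[200:200] = list(rng.choice(list(AA), 12))
    aln = align_to_reference(ProteinRecord("mut", "".join(seq)), rcsad1)
    mapped = [q for q in (aln.column_map[p] for p in sorted(aln.column_map)) if q]
    assert mapped == sorted(mapped)


def test_reference_self_signature(rcsad1):
    aln = align_to_reference(rcsad1, rcsad1)
    sig = extract_signature(aln)
    assert sig.as_string() == POCKET_RESIDUES
    assert sig.query_positions == POCKET_POSITIONS


def test_insertion_before_pocket_shifts_positions(rcsad1):
    query = ProteinRecord("ins", rcsad1.sequence[:100] + "W" + rcsad1.sequence[100:])
    sig = extract_signature(align_to_reference(query, rcsad1))
    assert sig.as_string() == POCKET_RESIDUES
    assert sig.query_positions == tuple(p + 1 for p in POCKET_POSITIONS)


def test_deletion_of_first_pocket_cluster_yields_gaps(rcsad1):
    # remove residues 114-118 (1-based) entirely
    seq = rcsad1.sequence[:113] + rcsad1.sequence[118:]
    sig = extract_signature(align_to_reference(ProteinRecord("del", seq), rcsad1))
    assert sig.residues[:4] == (GAP,) * 4
    assert sig.residues[4:] == tuple(POCKET_RESIDUES[4:])
    assert not sig.is_complete


def test_signature_invariant_to_substitutions_outside_pocket(rcsad1):
    rng = np.random.default_rng(31)
    seq = list(rcsad1.sequence)
    pocket0 = {p - 1 for p in POCKET_POSITIONS}
    for _ in range(25):
        i = int(rng.integers(0, len(seq)))
        if i in pocket0:
            continue
        seq[i] = rng.choice([a for a in AA if a != seq[i]])
    sig = extract_signature(align_to_reference(ProteinRecord("sub", "".join(seq)), rcsad1))
    assert sig.as_string() == POCKET_RESIDUES
    assert sig.query_positions == POCKET_POSITIONS


def test_extract_requires_matching_reference(rcsad1):
    aln = align_to_reference(rcsad1, ProteinRecord("other", rcsad1.sequence))
    with pytest.raises(ValidationError, match="reference"):
        extract_signature(aln, ReferencePocket())


def test_pocket_positions_must_increase():
    with pytest.raises(ValidationError):
        ReferencePocket(positions=(114, 113), canonical_residues="ML")
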