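import numpy as np
import pytest

from desatsig.errors import ValidationError
from desatsig.pocket_map import GAP, PocketSignature
from desatsig.specificity import (
    OMEGA7,
    OMEGA9,
    UNRESOLVED,
    ArchetypeProfile,
    ReferencePanel,
    classify,
    group_family,
    signature_identity,
    table_signatures,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def sig(name, residues):
    return PocketSignature(name, tuple(residues), tuple(range(1, len(residues) + 1)))


def test_archetype_signature_is_omega9():
    call = classify(sig("RcSAD1", "MLTLPTGF"))
    assert call.call == OMEGA9
    assert call.archetype_matches == 8
    assert call.per_reference_identity["RcSAD1"] == 1.0


def test_divergent_carboxy_cluster_is_omega7_candidate(pocket_table):
    residues = pocket_table["family"]["GhD-SAD8"]["residues"]
    call = classify(sig("GhD-SAD8", residues))
    assert call.call == OMEGA7
    assert call.archetype_matches == 4  # divergent at 179, 181, 188, 189


def test_gap_makes_unresolved():
    call = classify(sig("g", [GAP] * 8))
    assert call.call == UNRESOLVED
    call = classify(sig("g", list("MLTLPTG") + [GAP]))
    assert call.call == UNRESOLVED


def test_wrong_signature_length_errors():
    with pytest.raises(ValidationError, match="residues"):
        classify(sig("g", "MLT"))


def test_identity_matches_bruteforce_positionwise():
    rng = np.random.default_rng(5)
    panel = ReferencePanel.default()
    for _ in range(50):
        letters = rng.choice(list(AA), 8)
        call = classify(sig("r", letters))
        for ref_id, ref_sig in panel.entries.items():
            expected = sum(a == b for a, b in zip(letters, ref_sig.residues)) / 8
            assert call.per_reference_identity[ref_id] == expected


def test_reference_panel_members_classify_to_their_known_specificity(pocket_table):
    expected = {
        "RcSAD1": OMEGA9,
        "AtFAB2": OMEGA9,
        "AtAAD2": OMEGA7,
        "AtAAD3": OMEGA7,
        "Muc-PAD": OMEGA7,
    }
    for ref_id, want in expected.items():
        residues = pocket_table["references"][ref_id]["residues"]
        assert classify(sig(ref_id, residues)).call == want


def test_family_table_partitions_ten_seven():
    summary = group_family([classify(s) for s in table_signatures()])
    assert summary.counts == {OMEGA9: 10, OMEGA7: 7, UNRESOLVED: 0}
    assert summary.members[OMEGA7] == (
        "GhA-SAD5", "GhA-SAD6", "GhA-SAD7",
        "GhD-SAD4", "GhD-SAD5", "GhD-SAD7", "GhD-SAD8",
    )


def test_group_family_order_invariant():
    calls = [classify(s) for s in table_signatures()]
    rng = np.random.default_rng(2)
    shuffled = [calls[i] for i in rng.permutation(len(calls))]
    assert group_family(calls) == group_family(shuffled)


def test_group_family_duplicate_ids_rejected():
    c = classify(sig("dup", "MLTLPTGF"))
    with pytest.raises(ValidationError, match="duplicate"):
        group_family([c, c])


def test_all_archetype_copies_give_single_class():
    calls = [classify(sig(f"g{i}", "MLTLPTGF")) for i in range(5)]
    summary = group_family(calls)
    assert summary.counts == {OMEGA9: 5, OMEGA7: 0, UNRESOLVED: 0}


def test_classification_is_pure_function_of_signature():
    a = classify(sig("x", "MLTLMAAY"))
    b = classify(sig("x", "MLTLMAAY"))
    assert a == b


def test_divergent_pair_identity_is_five_of_eight(pocket_table):
    """The two confirmed 16:0-specific enzymes share 5/8 pocket residues."""
    a = sig("GhA-SAD6", pocket_table["family"]["GhA-SAD6"]["residues"])
    b = sig("GhD-SAD8", pocket_table["family"]["GhD-SAD8"]["residues"])
    assert signature_identity(a, b) == 5 / 8


def test_strict_archetype_reclassifies_isoleucine_variants(pocket_table):
    strict = ArchetypeProfile.strict()
    default = ArchetypeProfile.default()
    residues = pocket_table["family"]["GhA-SAD1"]["residues"]  # I at position 115
    assert classify(sig("GhA-SAD1", residues), default).call == OMEGA9
    assert classify(sig("GhA-SAD1", residues), strict).call == OMEGA7
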