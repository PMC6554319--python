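import numpy as np
import pandas as pd
import pytest

from desatsig.cis_scan import scan_promoter
from desatsig.errors import SpecError
from desatsig.pocket_map import POCKET_POSITIONS, POCKET_RESIDUES
from desatsig.synthetic_data import (
    ALLOWED_SETS,
    FamilySpec,
    GeneSpec,
    PanelSpec,
    PromoterSpec,
    gen_family,
    gen_promoters,
    gen_quant_panel,
)


def test_seed_is_mandatory():
    with pytest.raises(SpecError):
        FamilySpec(genes=(GeneSpec("g", "omega9"),), seed=None)
    with pytest.raises(SpecError):
        PanelSpec(seed=None)


def test_same_seed_byte_identical():
    spec = FamilySpec.random(2, 2, seed=77, n_indels=2)
    r1, t1 = gen_family(spec)
    r2, t2 = gen_family(spec)
    assert [(a.id, a.sequence) for a in r1] == [(b.id, b.sequence) for b in r2]
    pd.testing.assert_frame_equal(t1, t2)
    pspec = PromoterSpec(plants={"g": {"skn-1": 2}}, seed=5)
    assert gen_promoters(pspec)[0][0].sequence == gen_promoters(pspec)[0][0].sequence
    qspec = PanelSpec(seed=5)
    cq1, pk1, _ = gen_quant_panel(qspec)
    cq2, pk2, _ = gen_quant_panel(qspec)
    pd.testing.assert_frame_equal(cq1, cq2)
    pd.testing.assert_frame_equal(pk1, pk2)


def test_planted_classes_respect_constraints():
    _, truth = gen_family(FamilySpec.random(6, 6, seed=3))
    for _, row in truth.iterrows():
        letters = [row[f"res{p}"] for p in POCKET_POSITIONS]
        inside = all(l in s for l, s in zip(letters, ALLOWED_SETS))
        if row["class"] == "omega9":
            assert inside
        else:
            assert not inside


def test_zero_mutation_zero_indel_gene_equals_reference(rcsad1):
    spec = FamilySpec(
        genes=(GeneSpec("copy", "omega9",
                        pocket_overrides=dict(zip(POCKET_POSITIONS, POCKET_RESIDUES))),),
        seed=1,
        background_sub_rate=0.0,
    )
    records, truth = gen_family(spec)
    assert records[0].sequence == rcsad1.sequence
    assert tuple(truth.iloc[0][f"pos{p}"] for p in POCKET_POSITIONS) == POCKET_POSITIONS


def test_truth_positions_point_at_planted_letters():
    _, truth = gen_family(FamilySpec.random(2, 2, seed=19, n_indels=3))
    records, truth = gen_family(FamilySpec.random(2, 2, seed=19, n_indels=3))
    seqs = {r.id: r.sequence for r in records}
    for _, row in truth.iterrows():
        for p in POCKET_POSITIONS:
            assert seqs[row["gene"]][int(row[f"pos{p}"]) - 1] == row[f"res{p}"]


def test_invalid_omega9_override_rejected():
    spec = FamilySpec(
        genes=(GeneSpec("bad", "omega9", pocket_overrides={117: "R"}),), seed=1
    )
    with pytest.raises(SpecError, match="allowed set"):
        gen_family(spec)


def test_omega7_override_must_diverge():
    spec = FamilySpec(
        genes=(GeneSpec("bad", "omega7",
                        pocket_overrides=dict(zip(POCKET_POSITIONS, POCKET_RESIDUES))),),
        seed=1,
    )
    with pytest.raises(SpecError, match="archetype"):
        gen_family(spec)


def test_non_family_fails_domain_scan():
    from desatsig.domain_scan import scan_protein

    records, truth = gen_family(FamilySpec.random(1, 0, seed=2, n_non_family=2))
    for rec in records:
        klass = truth.set_index("gene").loc[rec.id, "class"]
        assert scan_protein(rec).positive == (klass != "non_family")


def test_promoter_truth_counts_recovered_exactly():
    spec = PromoterSpec(plants={"a": {"skn-1": 3, "GCN4": 1}, "b": {}}, seed=8)
    records, truth = gen_promoters(spec)
    by_gene = {r.gene_id: r for r in records}
    hits_a, ann_a = scan_promoter(by_gene["a"])
    assert ann_a.counts == {"skn-1": 3, "GCN4": 1}
    planted = {
        (row.motif, row.start, row.strand) for row in truth.itertuples() if row.gene == "a"
    }
    assert {(h.motif_name, h.start, h.strand) for h in hits_a} == planted
    _, ann_b = scan_promoter(by_gene["b"])
    assert not ann_b.endosperm_flag and sum(ann_b.counts.values()) == 0


def test_promoter_capacity_error():
    with pytest.raises(SpecError, match="fit"):
        gen_promoters(PromoterSpec(plants={"g": {"skn-1": 200}}, seed=1, length=400))


def test_promoter_length_and_alphabet():
    records, _ = gen_promoters(PromoterSpec(plants={"g": {"skn-1": 1}}, seed=3))
    assert len(records[0]) == 2000
    assert set(records[0].sequence) <= set("ACGT")


def test_panel_coupling_zero_gives_null_correlation():
    from desatsig import expression_quant, fame_quant
    from desatsig.association import associate_panel

    rs = []
    for seed in range(25):
        spec = PanelSpec(seed=600 + seed, tissues=("endosperm",), coupling=0.0)
        cq, peaks, _ = gen_quant_panel(spec)
        rq = expression_quant.relative_expression(
            expression_quant.CqTable(cq, calibrator=spec.calibrator)
        )
        prof = fame_quant.to_profile(peaks)
        out = associate_panel(rq, prof, [(spec.coupled_gene, "16:1")])
        rs.append(out.loc[0, "r"])
    assert abs(np.mean(rs)) < 0.12
    assert np.mean(np.abs(rs)) < 0.35


def test_panel_reference_genes_are_stable():
    spec = PanelSpec(seed=44)
    cq, _, _ = gen_quant_panel(spec)
    for ref, base in spec.reference_genes:
        vals = cq.loc[cq["gene"] == ref, "cq"]
        assert abs(vals.mean() - base) < 0.15
        assert vals.std() < 3 * spec.cq_noise_sd
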