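import numpy as np
import pandas as pd
import pytest

from desatsig.errors import SchemaError, ValidationError
from desatsig.expression_quant import CqTable, relative_expression
from desatsig.synthetic_data import PanelSpec, gen_quant_panel


def make_cq(rows):
    return pd.DataFrame(rows, columns=["gene", "sample", "replicate", "cq"])


REFS = ("ref1", "ref2")


def two_sample_table(target_cal, target_s, refs_cal=(20, 20), refs_s=(20, 20)):
    rows = [
        ("t", "cal", 1, target_cal),
        ("t", "s", 1, target_s),
        ("ref1", "cal", 1, refs_cal[0]),
        ("ref2", "cal", 1, refs_cal[1]),
        ("ref1", "s", 1, refs_s[0]),
        ("ref2", "s", 1, refs_s[1]),
    ]
    return CqTable(make_cq(rows), reference_genes=REFS, calibrator="cal")


def test_equal_cq_gives_unit_rq():
    out = relative_expression(two_sample_table(26, 26))
    assert np.allclose(out["rq"], 1.0)


def test_worked_example_two_cycles_earlier_is_fourfold():
    out = relative_expression(two_sample_table(target_cal=26, target_s=24))
    row = out[out["sample"] == "s"].iloc[0]
    assert row["delta_delta_cq"] == pytest.approx(-2.0)
    assert row["rq"] == pytest.approx(4.0)


def test_calibrator_rq_exactly_one():
    spec = PanelSpec(seed=5, tissues=("endosperm",))
    cq, _, _ = gen_quant_panel(spec)
    out = relative_expression(CqTable(cq, calibrator=spec.calibrator))
    cal = out[out["sample"] == spec.calibrator]
    assert (cal["rq"] == 1.0).all()


def test_global_cq_shift_leaves_rq_unchanged():
    spec = PanelSpec(seed=6, tissues=("endosperm",))
    cq, _, _ = gen_quant_panel(spec)
    base = relative_expression(CqTable(cq, calibrator=spec.calibrator))
    shifted = cq.assign(cq=cq["cq"] + 3.7)
    out = relative_expression(CqTable(shifted, calibrator=spec.calibrator))
    assert np.allclose(base["rq"], out["rq"])


def test_reference_gene_order_is_irrelevant():
    t1 = two_sample_table(26, 23, refs_s=(19, 21))
    t2 = CqTable(t1.data, reference_genes=("ref2", "ref1"), calibrator="cal")
    pd.testing.assert_frame_equal(relative_expression(t1), relative_expression(t2))


def test_rq_monotone_decreasing_in_target_cq():
    rqs = [
        relative_expression(two_sample_table(26, c)).set_index("sample").loc["s", "rq"]
        for c in (22, 24, 26, 28)
    ]
    assert rqs == sorted(rqs, reverse=True)


def test_missing_reference_in_sample_names_it():
    rows = [
        ("t", "cal", 1, 26), ("t", "s", 1, 24),
        ("ref1", "cal", 1, 20), ("ref2", "cal", 1, 20),
        ("ref1", "s", 1, 20),
    ]
    with pytest.raises(ValidationError, match=r"ref2.*\['s'\]"):
        CqTable(make_cq(rows), reference_genes=REFS, calibrator="cal")


def test_missing_calibrator_rejected():
    rows = [("t", "s", 1, 24), ("ref1", "s", 1, 20), ("ref2", "s", 1, 20)]
    with pytest.raises(ValidationError, match="calibrator"):
        CqTable(make_cq(rows), reference_genes=REFS, calibrator="cal")
    with pytest.raises(ValidationError, match="calibrator"):
        CqTable(make_cq(rows), reference_genes=REFS, calibrator="")


def test_schema_enforced():
    with pytest.raises(SchemaError, match="cq"):
        CqTable(pd.DataFrame({"gene": [], "sample": [], "replicate": []}), calibrator="c")


def test_recovery_from_noisy_replicates_within_tolerance():
    """Cq noise sd 0.2 with triplicates: typical rq error well under 15 percent."""
    errors = []
    for seed in range(4):
        spec = PanelSpec(seed=seed, tissues=("endosperm",), bio_sd_log2=0.0)
        cq, _, truth = gen_quant_panel(spec)
        out = relative_expression(CqTable(cq, calibrator=spec.calibrator))
        latent = truth["expression"].set_index(["gene", "sample"])["latent"]
        for _, row in out.iterrows():
            expected = latent[(row["gene"], row["sample"])] / latent[
                (row["gene"], spec.calibrator)
            ]
            errors.append(abs(row["rq"] - expected) / expected)
    assert np.median(errors) <= 0.15


def test_noiseless_panel_recovers_planted_folds_exactly():
    spec = PanelSpec(seed=9, cq_noise_sd=0.0, bio_sd_log2=0.0)
    cq, _, truth = gen_quant_panel(spec)
    out = relative_expression(CqTable(cq, calibrator=spec.calibrator))
    latent = truth["expression"].set_index(["gene", "sample"])["latent"]
    for _, row in out.iterrows():
        expected = latent[(row["gene"], row["sample"])] / latent[
            (row["gene"], spec.calibrator)
        ]
        assert row["rq"] == pytest.approx(expected, rel=1e-9)
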