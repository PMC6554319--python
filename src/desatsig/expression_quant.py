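"""Relative expression from qPCR Cq tables by the 2^-ΔΔCq method.

Replicates are averaged on the Cq scale; the two reference genes (defaults
EF-1a and Histone3) are combined per sample by the arithmetic mean of their
mean Cq, which is the geometric mean on the quantity scale.  ΔCq is target
minus reference aggregate, ΔΔCq subtracts the calibrator sample's ΔCq, and
relative quantity is 2^-ΔΔCq — so every target is exactly 1 in the calibrator.
The calibrator is a required explicit input; results are calibrator-relative
by construction.  Replicate dispersion (sd of Cq) is reported, not propagated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .seq_io import CQ_COLUMNS

DEFAULT_REFERENCE_GENES = ("EF-1a", "Histone3")

CQ_PLAUSIBLE_RANGE = (10.0, 40.0)


@dataclass
class CqTable:
    """Long-format Cq measurements plus the normalization scheme."""

    data: pd.DataFrame
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES
    calibrator: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CQ_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(
                f"Cq table missing column(s) {missing}; expected {list(CQ_COLUMNS)}"
            )
        if not self.calibrator:
            raise ValidationError("a calibrator sample must be named explicitly")
        cq = pd.to_numeric(self.data["cq"], errors="coerce")
        if cq.isna().any():
            raise ValidationError("non-numeric or missing cq values in table")
        self.data = self.data.assign(cq=cq)
        lo, hi = CQ_PLAUSIBLE_RANGE
        n_out = int(((cq < lo) | (cq > hi)).sum())
        if n_out:
            warnings.warn(
                f"{n_out} Cq value(s) outside the plausible range [{lo}, {hi}]",
                stacklevel=2,
            )
        samples = set(self.data["sample"].unique())
        if self.calibrator not in samples:
            raise ValidationError(f"calibrator sample {self.calibrator!r} not in table")
        for ref in self.reference_genes:
            ref_samples = set(self.data.loc[self.data["gene"] == ref, "sample"])
            absent = samples - ref_samples
            if absent:
                raise ValidationError(
                    f"reference gene {ref!r} missing in sample(s) {sorted(absent)}"
                )

    @property
    def target_genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - set(self.reference_genes))


def relative_expression(table: CqTable) -> pd.DataFrame:
    """Compute 2^-ΔΔCq per (target gene, sample).

    Returns columns ``gene, sample, mean_cq, sd_cq, delta_cq, delta_delta_cq,
    rq``, one row per target gene per sample.
    """
    df = table.data
    per_gs = (
        df.groupby(["gene", "sample"])["cq"]
        .agg(mean_cq="mean", sd_cq="std", n_replicates="size")
        .reset_index()
    )
    per_gs["sd_cq"] = per_gs["sd_cq"].fillna(0.0)  # single replicate -> sd 0

    is_ref = per_gs["gene"].isin(table.reference_genes)
    ref_aggregate = (
        per_gs[is_ref].groupby("sample")["mean_cq"].mean().rename("ref_cq")
    )
    targets = per_gs[~is_ref].merge(ref_aggregate, on="sample")
    targets["delta_cq"] = targets["mean_cq"] - targets["ref_cq"]

    cal = targets[targets["sample"] == table.calibrator][["gene", "delta_cq"]]
    cal = cal.rename(columns={"delta_cq": "cal_delta_cq"})
    missing_in_cal = set(targets["gene"]) - set(cal["gene"])
    if missing_in_cal:
        raise ValidationError(
            f"target gene(s) {sorted(missing_in_cal)} not measured in calibrator "
            f"sample {table.calibrator!r}"
        )
    out = targets.merge(cal, on="gene")
    out["delta_delta_cq"] = out["delta_cq"] - out["cal_delta_cq"]
    out["rq"] = np.exp2(-out["delta_delta_cq"])
    out = out.sort_values(["gene", "sample"]).reset_index(drop=True)
    return out[
        ["gene", "sample", "mean_cq", "sd_cq", "delta_cq", "delta_delta_cq", "rq"]
    ]
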