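"""Expression-lipid association across tissue/stage samples.

For a (gene, fatty-acid species) pair the paired series of relative expression
(2^-ΔΔCq) and composition (percent of total fatty acids) over matched samples
is summarized by the Pearson correlation, an ordinary least-squares fit of
composition on expression, and the two-sided t-test of r = 0 on n-2 degrees of
freedom.  Pearson (not rank) correlation matches the linear-regression framing
of the question; samples are joined by exact key, replicate-level by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, ValidationError

MIN_N = 3


@dataclass(frozen=True)
class AssociationResult:
    gene_id: str
    species: str
    tissue: str
    r: float
    slope: float
    intercept: float
    n: int
    p_value: float
    aggregation: str = "replicate"


def correlate(
    expression: Sequence[float],
    fa_mol_percent: Sequence[float],
    gene_id: str = "",
    species: str = "",
    tissue: str = "all",
    aggregation: str = "replicate",
) -> AssociationResult:
    """Pearson r, OLS fit and p-value for one paired series.

    Raises :class:`UndefinedCorrelationError` for n < 3 or zero variance in
    either variable (rather than propagating NaN).
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(fa_mol_percent, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("expression and composition series must be equal-length 1-D")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in paired series")
    n = len(x)
    if n < MIN_N:
        raise UndefinedCorrelationError(f"need at least {MIN_N} pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "zero variance in expression or composition; correlation undefined"
        )
    fit = stats.linregress(x, y)
    return AssociationResult(
        gene_id=gene_id,
        species=species,
        tissue=tissue,
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=n,
        p_value=float(fit.pvalue),
        aggregation=aggregation,
    )


def associate_panel(
    expression: pd.DataFrame,
    profiles: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    tissue_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Correlate each requested (gene, species) pair over matched samples.

    ``expression`` needs columns gene/sample/rq; ``profiles`` needs
    sample/species/mol_percent.  Samples are matched by exact key; unmatched
    samples are dropped (their count is recorded in the ``n_dropped`` column).
    ``tissue_labels`` optionally maps sample -> tissue, yielding one result per
    pair per tissue.
    """
    for col in ("gene", "sample", "rq"):
        if col not in expression.columns:
            raise ValidationError(f"expression table missing column {col!r}")
    for col in ("sample", "species", "mol_percent"):
        if col not in profiles.columns:
            raise ValidationError(f"profile table missing column {col!r}")
    rows = []
    for gene, species in pairs:
        expr = expression[expression["gene"] == gene][["sample", "rq"]]
        fa = profiles[profiles["species"] == species][["sample", "mol_percent"]]
        joined = expr.merge(fa, on="sample", how="inner")
        n_dropped = (len(expr) - len(joined)) + (len(fa) - len(joined))
        if joined.empty:
            raise ValidationError(
                f"no overlapping samples for pair ({gene!r}, {species!r})"
            )
        if tissue_labels is None:
            groups = [("all", joined)]
        else:
            joined = joined.assign(tissue=joined["sample"].map(tissue_labels))
            groups = list(joined.groupby("tissue"))
        for tissue, sub in groups:
            res = correlate(
                sub["rq"].to_numpy(),
                sub["mol_percent"].to_numpy(),
                gene_id=gene,
                species=species,
                tissue=str(tissue),
            )
            rows.append(
                {
                    "gene": gene,
                    "species": species,
                    "tissue": res.tissue,
                    "r": res.r,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "n": res.n,
                    "p_value": res.p_value,
                    "aggregation": res.aggregation,
                    "n_dropped": n_dropped,
                }
            )
    return pd.DataFrame(rows)
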