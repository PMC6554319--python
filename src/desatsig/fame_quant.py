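"""Fatty-acid composition from GC-FAME peak areas.

Peak areas per (sample, species) are normalized to composition (percent of
total fatty acids) with the C17:0 internal standard excluded from the total.
Two modes:

* ``area`` (default) — shares of raw peak area, matching plain peak-area
  normalization;
* ``molar`` — areas divided by methyl-ester molar mass before normalization,
  a mole-fraction correction using the packaged mass table.

When the amount of internal standard added is known, absolute mass per species
is also reported as ``(area / istd_area) * istd_mass``.
"""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError, ValidationError
from .resources import load_fame_masses
from .seq_io import PEAK_COLUMNS

ISTD_SPECIES = "17:0"

#: Relative tolerance on the per-sample composition total.
SUM_RTOL = 1e-9


def to_profile(
    peaks: pd.DataFrame,
    masses: dict[str, float] | None = None,
    mode: str = "area",
    istd_species: str = ISTD_SPECIES,
    istd_mass: float | None = None,
) -> pd.DataFrame:
    """Convert a peak table to percent composition per sample.

    Returns columns ``sample, species, mol_percent`` (plus ``mass_micrograms``
    when ``istd_mass`` is given).  The internal standard never appears in the
    output; per-sample percentages sum to 100 exactly up to float rounding.
    """
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise SchemaError(
            f"peak table missing column(s) {missing}; expected {list(PEAK_COLUMNS)}"
        )
    if mode not in ("area", "molar"):
        raise ValueError(f"mode must be 'area' or 'molar', got {mode!r}")
    df = peaks.copy()
    df["area"] = pd.to_numeric(df["area"], errors="coerce")
    if df["area"].isna().any():
        raise ValidationError("non-numeric or missing peak areas")
    if (df["area"] < 0).any():
        raise ValidationError("negative peak areas")

    istd = df[df["species"] == istd_species]
    body = df[df["species"] != istd_species].copy()
    if body.empty:
        raise ValidationError("no non-internal-standard species in peak table")

    if mode == "molar":
        masses = masses or load_fame_masses()
        unknown = sorted(set(body["species"]) - set(masses))
        if unknown:
            raise ValidationError(
                f"species without molar mass in molar mode: {unknown}"
            )
        body["weight"] = body["area"] / body["species"].map(masses)
    else:
        body["weight"] = body["area"]

    totals = body.groupby("sample")["weight"].transform("sum")
    if (totals <= 0).any():
        bad = sorted(body.loc[totals <= 0, "sample"].unique())
        raise ValidationError(f"sample(s) with zero total area: {bad}")
    body["mol_percent"] = body["weight"] / totals * 100.0

    if istd_mass is not None:
        istd_areas = istd.set_index("sample")["area"]
        missing_istd = sorted(set(body["sample"]) - set(istd_areas.index))
        if missing_istd:
            raise ValidationError(
                f"internal standard {istd_species!r} absent in sample(s) {missing_istd}"
            )
        if (istd_areas <= 0).any():
            bad = sorted(istd_areas[istd_areas <= 0].index)
            raise ValidationError(f"internal standard area is zero in sample(s) {bad}")
        body["mass_micrograms"] = (
            body["area"] / body["sample"].map(istd_areas) * float(istd_mass)
        )
        cols = ["sample", "species", "mol_percent", "mass_micrograms"]
    else:
        cols = ["sample", "species", "mol_percent"]
    return body.sort_values(["sample", "species"]).reset_index(drop=True)[cols]
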