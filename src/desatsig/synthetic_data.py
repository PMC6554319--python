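"""Ground-truth generators for every pipeline input.

Three generators emulate the statistical structure the analysis assumes, so
each stage can be scored against a planted truth without any external data:

* :func:`gen_family` — a desaturase family derived from the packaged archetype
  scaffold: omega-9 members stay inside the archetype's allowed pocket sets,
  omega-7 members carry divergent pocket residues, and background
  substitutions/indels never touch the eight pocket columns (indels keep a
  configurable margin so numbering transfer is well defined).
* :func:`gen_promoters` — 2-kb upstream regions whose background is scrubbed
  of accidental motif cores on either strand before the requested motif
  occurrences are planted at recorded positions, making truth counts exact.
* :func:`gen_quant_panel` — a two-tissue, four-stage developing-seed panel:
  Cq values follow ``base - log2(expression) + noise`` with two stable
  reference genes, and the 16:1 fraction of the endosperm fatty-acid profile
  tracks a designated gene's expression through a linear coupling.

Every generator takes a mandatory integer seed and drives a single
``numpy.random.default_rng``; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cis_scan import DEFAULT_MOTIFS, MotifDefinition, revcomp, scan_promoter
from .errors import SpecError
from .pocket_map import POCKET_POSITIONS, POCKET_RESIDUES
from .resources import get_rcsad1, load_pocket_table, numbering_offset
from .seq_io import ProteinRecord, PromoterRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Archetype-compatible residues per pocket position (ascending order).
ALLOWED_SETS = ({"M"}, {"L", "I"}, {"T"}, {"L"}, {"P"}, {"T"}, {"G"}, {"F"})

#: Divergent residues observed among characterized omega-7 enzymes, per
#: position; position 115 never diverges in the characterized set.
DIVERGENT_POOLS = (
    ("I", "L", "T"),
    (),
    ("R",),
    ("W", "M"),
    ("S", "V", "M"),
    ("F", "I", "A", "S"),
    ("T", "A"),
    ("A", "Y"),
)

OMEGA9 = "omega9"
OMEGA7 = "omega7"
NON_FAMILY = "non_family"


# ---------------------------------------------------------------------------
# Protein family
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    name: str
    klass: str  # omega9 | omega7 | non_family
    pocket_overrides: Mapping[int, str] = field(default_factory=dict)
    n_indels: int = 0
    n_term_ext: int = 0

    def __post_init__(self) -> None:
        if self.klass not in (OMEGA9, OMEGA7, NON_FAMILY):
            raise SpecError(f"unknown class {self.klass!r} for gene {self.name!r}")
        for pos in self.pocket_overrides:
            if pos not in POCKET_POSITIONS:
                raise SpecError(
                    f"gene {self.name!r}: override position {pos} is not a pocket column"
                )


@dataclass(frozen=True)
class FamilySpec:
    genes: tuple[GeneSpec, ...]
    seed: int
    background_sub_rate: float = 0.02
    indel_margin: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SpecError("seed is mandatory")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise SpecError("duplicate gene names in family spec")

    @classmethod
    def random(
        cls,
        n_omega9: int,
        n_omega7: int,
        seed: int,
        n_non_family: int = 0,
        n_indels: int = 0,
        **kwargs,
    ) -> "FamilySpec":
        genes = []
        for i in range(n_omega9):
            genes.append(GeneSpec(f"O9-{i+1:02d}", OMEGA9, n_indels=n_indels))
        for i in range(n_omega7):
            genes.append(GeneSpec(f"O7-{i+1:02d}", OMEGA7, n_indels=n_indels))
        for i in range(n_non_family):
            genes.append(GeneSpec(f"BG-{i+1:02d}", NON_FAMILY))
        return cls(genes=tuple(genes), seed=seed, **kwargs)


def _sample_pocket_letters(gene: GeneSpec, rng: np.random.Generator) -> tuple[str, ...]:
    letters = list(POCKET_RESIDUES)
    if gene.klass == OMEGA9:
        for i, allowed in enumerate(ALLOWED_SETS):
            pos = POCKET_POSITIONS[i]
            if pos in gene.pocket_overrides:
                letters[i] = gene.pocket_overrides[pos]
                if letters[i] not in allowed:
                    raise SpecError(
                        f"gene {gene.name!r}: omega9 override {letters[i]!r} at "
                        f"position {pos} outside allowed set {sorted(allowed)}"
                    )
            else:
                letters[i] = rng.choice(sorted(allowed))
    else:  # omega7
        for i, pos in enumerate(POCKET_POSITIONS):
            if pos in gene.pocket_overrides:
                letters[i] = gene.pocket_overrides[pos]
        if not gene.pocket_overrides:
            divergable = [i for i, pool in enumerate(DIVERGENT_POOLS) if pool]
            k = int(rng.integers(1, 5))
            chosen = rng.choice(divergable, size=min(k, len(divergable)), replace=False)
            for i in chosen:
                letters[i] = rng.choice(DIVERGENT_POOLS[i])
        divergent = sum(
            1 for i, res in enumerate(letters) if res not in ALLOWED_SETS[i]
        )
        if divergent == 0:
            raise SpecError(
                f"gene {gene.name!r}: omega7 overrides leave an archetype signature"
            )
    return tuple(letters)


def gen_family(spec: FamilySpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a protein family plus its truth table.

    The truth table has one row per gene: planted class, the eight planted
    pocket letters and their true 1-based positions in the emitted sequence
    (after indels); NaN positions for non-family background sequences.
    """
    rng = np.random.default_rng(spec.seed)
    scaffold = get_rcsad1().sequence
    records: list[ProteinRecord] = []
    truth_rows = []
    for gene in spec.genes:
        if gene.klass == NON_FAMILY:
            shuffled = "".join(rng.permutation(list(scaffold)))
            records.append(ProteinRecord(gene.name, shuffled, "synthetic background"))
            truth_rows.append(
                {"gene": gene.name, "class": NON_FAMILY,
                 **{f"res{p}": "" for p in POCKET_POSITIONS},
                 **{f"pos{p}": np.nan for p in POCKET_POSITIONS}}
            )
            continue
        letters = _sample_pocket_letters(gene, rng)
        seq = list(scaffold)
        pocket_idx0 = [p - 1 for p in POCKET_POSITIONS]
        for i0, res in zip(pocket_idx0, letters):
            seq[i0] = res
        # background substitutions outside the pocket columns
        pocket_set = set(pocket_idx0)
        for i0 in range(len(seq)):
            if i0 in pocket_set:
                continue
            if rng.random() < spec.background_sub_rate:
                choices = [a for a in AMINO_ACIDS if a != seq[i0]]
                seq[i0] = rng.choice(choices)
        if gene.n_term_ext:
            ext = [rng.choice(list(AMINO_ACIDS)) for _ in range(gene.n_term_ext)]
            seq = ext + seq
        pocket_pos = [p + gene.n_term_ext for p in POCKET_POSITIONS]  # 1-based
        # indels, kept indel_margin residues away from every pocket column
        for _ in range(gene.n_indels):
            forbidden = set()
            for p in pocket_pos:
                forbidden.update(range(p - spec.indel_margin, p + spec.indel_margin + 1))
            candidates = [
                i for i in range(2, len(seq))  # keep termini intact
                if i not in forbidden
            ]
            if not candidates:
                raise SpecError("no indel site available outside pocket margins")
            site = int(rng.choice(candidates))  # 1-based residue index
            if rng.random() < 0.5:  # insertion before `site`
                seq.insert(site - 1, rng.choice(list(AMINO_ACIDS)))
                pocket_pos = [p + 1 if p >= site else p for p in pocket_pos]
            else:  # deletion of residue `site`
                del seq[site - 1]
                pocket_pos = [p - 1 if p > site else p for p in pocket_pos]
        sequence = "".join(seq)
        for p, res in zip(pocket_pos, letters):
            assert sequence[p - 1] == res
        records.append(ProteinRecord(gene.name, sequence, f"synthetic {gene.klass}"))
        truth_rows.append(
            {"gene": gene.name, "class": gene.klass,
             **{f"res{p}": res for p, res in zip(POCKET_POSITIONS, letters)},
             **{f"pos{p}": q for p, q in zip(POCKET_POSITIONS, pocket_pos)}}
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterSpec:
    plants: Mapping[str, Mapping[str, int]]  # gene -> motif name -> count
    seed: int
    length: int = 2000
    gc: float = 0.35
    motifs: tuple[MotifDefinition, ...] = DEFAULT_MOTIFS
    random_strand: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SpecError("seed is mandatory")
        known = {m.name for m in self.motifs}
        for gene, wanted in self.plants.items():
            for name, count in wanted.items():
                if name not in known:
                    raise SpecError(f"gene {gene!r}: unknown motif {name!r}")
                if count < 0:
                    raise SpecError(f"gene {gene!r}: negative count for {name!r}")

    @classmethod
    def results_layout(cls, seed: int, skn1_count: int = 3) -> "PromoterSpec":
        """The published promoter landscape of the 17-member family.

        Six of the seven divergent-pocket genes carry multiple skn-1 motifs
        (GhD-SAD5 and GhD-SAD8 an additional GCN4); GhD-SAD4 carries neither;
        archetype-group promoters carry none.
        """
        table = load_pocket_table()
        plants: dict[str, dict[str, int]] = {g: {} for g in table["family"]}
        for gene in ("GhA-SAD5", "GhA-SAD6", "GhA-SAD7", "GhD-SAD5", "GhD-SAD7", "GhD-SAD8"):
            plants[gene] = {"skn-1": skn1_count}
        for gene in ("GhD-SAD5", "GhD-SAD8"):
            plants[gene]["GCN4"] = 1
        plants["GhD-SAD4"] = {}
        return cls(plants=plants, seed=seed)


_PLANT_GAP = 8  # min bases between planted spans, so plants cannot compound


def _sample_background(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=length, p=probs))


def _motif_spans(seq: str, motifs) -> list[tuple[str, int, str]]:
    found = []
    for motif in motifs:
        for core, strand in ((motif.core, "+"), (revcomp(motif.core), "-")):
            k = len(core)
            for i in range(len(seq) - k + 1):
                if seq[i : i + k] == core:
                    found.append((motif.name, i, strand))
    return found


def _generate_promoter(
    rng: np.random.Generator, spec: PromoterSpec, wanted: Mapping[str, int]
) -> tuple[str, list[tuple[str, int, str]]]:
    motif_by_name = {m.name: m for m in spec.motifs}
    plant_list: list[str] = []
    for name, count in sorted(wanted.items()):
        plant_list.extend([name] * count)
    total_span = sum(len(motif_by_name[n].core) + _PLANT_GAP for n in plant_list)
    if total_span > spec.length:
        raise SpecError(
            f"{len(plant_list)} planted motifs do not fit in a {spec.length}-bp promoter"
        )
    for _attempt in range(200):
        seq = _sample_background(rng, spec.length, spec.gc)
        # choose non-overlapping plant positions with a safety gap
        placements: list[tuple[str, int, str]] = []  # (motif, start, strand)
        occupied: list[tuple[int, int]] = []
        ok = True
        for name in plant_list:
            k = len(motif_by_name[name].core)
            placed = False
            for _try in range(500):
                start = int(rng.integers(0, spec.length - k + 1))
                if all(
                    start + k + _PLANT_GAP <= s or e + _PLANT_GAP <= start
                    for s, e in occupied
                ):
                    strand = "+" if not spec.random_strand or rng.random() < 0.5 else "-"
                    placements.append((name, start, strand))
                    occupied.append((start, start + k))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        for name, start, strand in placements:
            core = motif_by_name[name].core
            if strand == "-":
                core = revcomp(core)
            seq[start : start + len(core)] = list(core)
        planted = {(n, s, st) for n, s, st in placements}
        protected = set()
        for name, start, _ in placements:
            protected.update(range(start, start + len(motif_by_name[name].core)))
        # scrub accidental occurrences (background or junction artifacts)
        clean = False
        for _round in range(500):
            hits = set(_motif_spans("".join(seq), spec.motifs))
            extra = hits - planted
            if not extra:
                clean = len(hits) == len(planted)
                break
            fixable = False
            for name, start, _strand in extra:
                span = range(start, start + len(motif_by_name[name].core))
                editable = [i for i in span if i not in protected]
                if editable:
                    fixable = True
                    for i in editable:
                        seq[i] = rng.choice(list("ACGT"))
            if not fixable:
                break  # plant-plant artifact: reposition from scratch
        if clean:
            return "".join(seq), placements
    raise SpecError("could not generate a clean promoter in 200 attempts")


def gen_promoters(spec: PromoterSpec) -> tuple[list[PromoterRecord], pd.DataFrame]:
    """Generate promoters with exact planted motif occurrences.

    Returns the records and a truth table with one row per planted occurrence
    (gene, motif, start, strand); genes with zero plants contribute no rows
    but do get a promoter record.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    rows = []
    for gene in spec.plants:
        seq, placements = _generate_promoter(rng, spec, spec.plants[gene])
        records.append(PromoterRecord(gene, seq, "synthetic promoter"))
        for name, start, strand in placements:
            rows.append({"gene": gene, "motif": name, "start": start, "strand": strand})
    truth = pd.DataFrame(rows, columns=["gene", "motif", "start", "strand"])
    return records, truth


# ---------------------------------------------------------------------------
# Quantitative panel (Cq + FAME)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSpec:
    """Study design of the developing-seed panel.

    Defaults emulate the dissected-seed experiment: embryo and endosperm at
    15/25/35/45 days after flowering, six biological replicates per tissue and
    stage, qPCR in technical triplicate with two stable reference genes, and
    an endosperm 16:1 fraction linearly coupled to the designated gene's
    expression.
    """

    seed: int
    tissues: tuple[str, ...] = ("embryo", "endosperm")
    stages: tuple[int, ...] = (15, 25, 35, 45)
    bio_replicates: int = 6
    tech_replicates: int = 3
    gene_profiles: Mapping[str, Mapping[tuple[str, int], float]] = field(
        default_factory=dict
    )
    reference_genes: tuple[tuple[str, float], ...] = (("EF-1a", 19.0), ("Histone3", 21.0))
    base_cq: float = 24.0
    cq_noise_sd: float = 0.2
    bio_sd_log2: float = 0.25
    coupled_gene: str = "GhA-SAD6"
    coupled_species: str = "16:1"
    coupled_tissue: str = "endosperm"
    coupling: float = 0.9
    fa_baseline: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    fa_noise_sd: float = 1.7
    fa_jitter_frac: float = 0.05
    istd_area: float = 5.0e4
    total_area: float = 1.0e6

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SpecError("seed is mandatory")
        if self.tech_replicates < 2:
            raise SpecError("at least 2 technical replicates required")
        if not self.gene_profiles:
            object.__setattr__(self, "gene_profiles", _default_gene_profiles(self))
        if not self.fa_baseline:
            object.__setattr__(self, "fa_baseline", _DEFAULT_FA_BASELINE)
        for gene, profile in self.gene_profiles.items():
            for key, fold in profile.items():
                if fold <= 0:
                    raise SpecError(f"gene {gene!r}: non-positive fold at {key}")

    @property
    def calibrator(self) -> str:
        return f"{self.tissues[0]}_{self.stages[0]}DAF_r1"

    def sample_ids(self) -> list[tuple[str, str, int]]:
        return [
            (f"{t}_{s}DAF_r{k}", t, s)
            for t in self.tissues
            for s in self.stages
            for k in range(1, self.bio_replicates + 1)
        ]


_DEFAULT_FA_BASELINE = {
    "embryo": {"16:0": 26.0, "16:1": 0.5, "18:0": 3.0, "18:1": 14.0, "18:2": 52.0, "18:3": 4.5},
    "endosperm": {"16:0": 30.0, "16:1": 5.0, "18:0": 3.0, "18:1": 10.0, "18:2": 47.0, "18:3": 5.0},
}


def _default_gene_profiles(spec: PanelSpec) -> dict:
    """Mid-stage endosperm peak for the coupled gene, flat control otherwise."""
    endo = {15: 5.0, 25: 8.0, 35: 1.5, 45: 0.4}
    emb = {15: 0.5, 25: 0.6, 35: 0.3, 45: 0.1}
    flat = {15: 1.5, 25: 1.8, 35: 1.2, 45: 0.8}
    profiles: dict[str, dict[tuple[str, int], float]] = {
        spec.coupled_gene: {},
        "GhA-SAD7": {},
    }
    for s in spec.stages:
        if "endosperm" in spec.tissues:
            profiles[spec.coupled_gene][("endosperm", s)] = endo.get(s, 1.0)
            profiles["GhA-SAD7"][("endosperm", s)] = flat.get(s, 1.0)
        if "embryo" in spec.tissues:
            profiles[spec.coupled_gene][("embryo", s)] = emb.get(s, 0.3)
            profiles["GhA-SAD7"][("embryo", s)] = flat.get(s, 1.0)
    return profiles


def gen_quant_panel(spec: PanelSpec):
    """Generate (Cq table, FAME peak table, truth) for the panel design.

    Truth is a dict with ``expression`` (gene, sample, latent expression on
    the calibrator-free fold scale), ``composition`` (sample, species, true
    percent), ``calibrator`` and ``coupling``.
    """
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_ids()
    genes = sorted(spec.gene_profiles)
    cq_rows = []
    latent: dict[tuple[str, str], float] = {}
    for gene in genes:
        profile = spec.gene_profiles[gene]
        for sample, tissue, stage in samples:
            fold = profile.get((tissue, stage))
            if fold is None:
                raise SpecError(f"gene {gene!r}: no fold for ({tissue!r}, {stage})")
            level = fold * float(np.exp2(spec.bio_sd_log2 * rng.standard_normal()))
            latent[(gene, sample)] = level
            for rep in range(1, spec.tech_replicates + 1):
                cq = spec.base_cq - np.log2(level) + spec.cq_noise_sd * rng.standard_normal()
                cq_rows.append(
                    {"gene": gene, "sample": sample, "replicate": rep, "cq": float(cq)}
                )
    for ref_gene, ref_base in spec.reference_genes:
        for sample, _tissue, _stage in samples:
            for rep in range(1, spec.tech_replicates + 1):
                cq = ref_base + spec.cq_noise_sd * rng.standard_normal()
                cq_rows.append(
                    {"gene": ref_gene, "sample": sample, "replicate": rep, "cq": float(cq)}
                )
    cq_table = pd.DataFrame(cq_rows)

    peak_rows = []
    comp_rows = []
    for sample, tissue, stage in samples:
        baseline = spec.fa_baseline[tissue]
        comp = {}
        for species, value in baseline.items():
            if species == spec.coupled_species and tissue == spec.coupled_tissue:
                continue
            jitter = float(np.exp(spec.fa_jitter_frac * rng.standard_normal()))
            comp[species] = value * jitter
        if tissue == spec.coupled_tissue:
            level = latent[(spec.coupled_gene, sample)]
            target = np.nan
            for _try in range(1000):
                noise = spec.fa_noise_sd * rng.standard_normal()
                target = baseline[spec.coupled_species] + spec.coupling * level + noise
                if 0.5 < target < 99.0:
                    break
            else:
                raise SpecError("coupled composition left (0, 100); adjust the spec")
            rest = sum(comp.values())
            scale = (100.0 - target) / rest
            comp = {sp: v * scale for sp, v in comp.items()}
            comp[spec.coupled_species] = float(target)
        else:
            total = sum(comp.values())
            comp = {sp: v / total * 100.0 for sp, v in comp.items()}
        if any(v <= 0 for v in comp.values()):
            raise SpecError("composition left (0, 100); adjust the spec")
        sample_scale = float(np.exp(0.2 * rng.standard_normal()))
        for species in sorted(comp):
            comp_rows.append(
                {"sample": sample, "species": species, "mol_percent": comp[species]}
            )
            peak_rows.append(
                {
                    "sample": sample,
                    "species": species,
                    "area": comp[species] / 100.0 * spec.total_area * sample_scale,
                }
            )
        peak_rows.append(
            {
                "sample": sample,
                "species": "17:0",
                "area": spec.istd_area * float(np.exp(0.1 * rng.standard_normal())),
            }
        )
    peaks = pd.DataFrame(peak_rows)
    expression_truth = pd.DataFrame(
        [{"gene": g, "sample": s, "latent": v} for (g, s), v in latent.items()]
    )
    truth = {
        "expression": expression_truth,
        "composition": pd.DataFrame(comp_rows),
        "calibrator": spec.calibrator,
        "coupling": spec.coupling,
    }
    return cq_table, peaks, truth


def gen_paired_series(r: float, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal pairs with population correlation ``r``."""
    if not -1.0 < r < 1.0:
        raise SpecError("r must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = z1
    y = r * z1 + np.sqrt(1.0 - r * r) * z2
    return x, y
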