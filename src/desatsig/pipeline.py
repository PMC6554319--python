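"""End-to-end candidate selection.

Stages: domain triage (PSSM) → global alignment to the archetype → pocket
signature extraction → archetype-rule classification → promoter cis-element
filter.  The final endosperm candidates are the proteins called
``omega7_candidate`` whose promoter carries at least one endosperm element
(skn-1 or GCN4).  A missing promoter leaves the classification intact but
excludes the gene from the final set — the two stages are independent lines
of evidence, so absence of promoter data is never treated as absence of the
element; it is recorded as ``promoter_missing``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import cis_scan, domain_scan, pocket_map, specificity
from .errors import ValidationError
from .resources import get_rcsad1
from .seq_io import ProteinRecord, PromoterRecord, read_fasta, write_table

logger = logging.getLogger(__name__)

#: Exit code for a run that succeeded but produced an empty report.
EXIT_EMPTY_REPORT = 3


@dataclass(frozen=True)
class PipelineConfig:
    scoring: pocket_map.ScoringScheme = field(default_factory=pocket_map.ScoringScheme)
    domain_threshold: float | None = None  # None = packaged calibrated threshold
    strands: str = "both"
    strict_archetype: bool = False

    def resolved(self) -> dict:
        profile = domain_scan.default_profile()
        return {
            "scoring": self.scoring.as_dict(),
            "domain_profile": profile.name,
            "domain_threshold": (
                profile.threshold if self.domain_threshold is None else self.domain_threshold
            ),
            "motifs": {m.name: m.core for m in cis_scan.DEFAULT_MOTIFS},
            "strands": self.strands,
            "archetype": "strict" if self.strict_archetype else "default",
            "reference": "RcSAD1",
        }

    def digest(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CandidateReport:
    table: pd.DataFrame
    summary: dict
    hits: list
    metadata: dict

    @property
    def final_candidates(self) -> list[str]:
        return sorted(self.table.loc[self.table["final_candidate"], "protein_id"])


def run_pipeline(
    proteins: str | Path | Sequence[ProteinRecord],
    promoters: str | Path | Sequence[PromoterRecord] | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> CandidateReport:
    """Run the full two-stage candidate selection.

    ``proteins``/``promoters`` may be FASTA paths or already-parsed records;
    ``promoters`` may be omitted entirely.  Every promoter gene id must match
    a protein id; proteins without a promoter stay classified but cannot
    become final candidates.
    """
    config = config or PipelineConfig()
    if isinstance(proteins, (str, Path)):
        proteins = read_fasta(proteins, alphabet="protein")
    proteins = list(proteins)
    if isinstance(promoters, (str, Path)):
        promoters = read_fasta(promoters, alphabet="dna")
    promoters = list(promoters) if promoters is not None else []

    protein_ids = {p.id for p in proteins}
    orphan = [p.gene_id for p in promoters if p.gene_id not in protein_ids]
    if orphan:
        raise ValidationError(f"promoter(s) without matching protein: {sorted(orphan)}")

    profile = domain_scan.default_profile()
    if config.domain_threshold is not None:
        profile = domain_scan.DomainProfile(
            profile.name, profile.scores, float(config.domain_threshold)
        )
    calls = domain_scan.scan_family(proteins, profile)
    positives = [p for p, c in zip(proteins, calls) if c.positive]
    logger.info("domain scan: %d/%d positive", len(positives), len(proteins))
    if not positives:
        warnings.warn("no protein passed the domain scan; report is empty", stacklevel=2)

    reference = get_rcsad1()
    pocket = pocket_map.ReferencePocket()
    pocket.check_reference(reference)
    signatures: dict[str, pocket_map.PocketSignature] = {}
    for protein in positives:
        aln = pocket_map.align_to_reference(protein, reference, config.scoring)
        signatures[protein.id] = pocket_map.extract_signature(aln, pocket)

    archetype = (
        specificity.ArchetypeProfile.strict()
        if config.strict_archetype
        else specificity.ArchetypeProfile.default()
    )
    panel = specificity.ReferencePanel.default()
    spec_calls = {
        pid: specificity.classify(sig, archetype, panel)
        for pid, sig in signatures.items()
    }
    logger.info("classified %d domain-positive proteins", len(spec_calls))

    all_hits: list[cis_scan.MotifHit] = []
    annotations: dict[str, cis_scan.PromoterAnnotation] = {}
    if promoters:
        all_hits, annot_list = cis_scan.annotate_family(
            promoters, strands=config.strands
        )
        annotations = {a.gene_id: a for a in annot_list}
    logger.info("promoter scan: %d promoters, %d hits", len(promoters), len(all_hits))

    rows = []
    for protein, call in zip(proteins, calls):
        sig = signatures.get(protein.id)
        spec_call = spec_calls.get(protein.id)
        annotation = annotations.get(protein.id)
        has_promoter = annotation is not None
        endosperm = annotation.endosperm_flag if has_promoter else None
        final = bool(
            spec_call is not None
            and spec_call.call == specificity.OMEGA7
            and endosperm is True
        )
        note = ""
        if spec_call is not None and spec_call.call == specificity.OMEGA7 and not has_promoter:
            note = "promoter_missing"
            logger.warning("omega7 candidate %s has no promoter record", protein.id)
        row = {
            "protein_id": protein.id,
            "domain_score": call.best_score,
            "domain_positive": call.positive,
            "signature": sig.as_string() if sig else "",
            "call": spec_call.call if spec_call else "",
            "archetype_matches": spec_call.archetype_matches if spec_call else pd.NA,
            "endosperm_flag": endosperm,
            "final_candidate": final,
            "note": note,
        }
        if spec_call:
            for ref_id, ident in spec_call.per_reference_identity.items():
                row[f"identity_{ref_id}"] = ident
        rows.append(row)
    table = pd.DataFrame(rows)

    summary_calls = [c for c in spec_calls.values()]
    if summary_calls:
        group_summary = specificity.group_family(summary_calls).to_dict()
    else:
        group_summary = {"counts": {}, "members": {}}
    summary = {
        "n_proteins": len(proteins),
        "n_domain_positive": len(positives),
        **group_summary["counts"],
        "n_final_candidates": int(table["final_candidate"].sum()),
        "final_candidates": sorted(
            table.loc[table["final_candidate"], "protein_id"]
        ),
        "members": group_summary["members"],
    }
    metadata = {
        "config": config.resolved(),
        "config_digest": config.digest(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    report = CandidateReport(table=table, summary=summary, hits=all_hits, metadata=metadata)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(table, outdir / "calls.tsv")
        sig_rows = []
        for pid, sig in signatures.items():
            row = {"protein_id": pid}
            for pos, res, qpos in zip(pocket.positions, sig.residues, sig.query_positions):
                row[f"p{pos}"] = res
                row[f"q{pos}"] = qpos if qpos is not None else ""
            sig_rows.append(row)
        write_table(pd.DataFrame(sig_rows), outdir / "signatures.tsv")
        bed = pd.DataFrame(
            cis_scan.hits_to_bed_rows(all_hits),
            columns=["chrom", "start", "end", "name", "score", "strand", "atg_offset"],
        )
        bed.to_csv(outdir / "hits.bed", sep="\t", index=False, header=False)
        annot_df = pd.DataFrame(
            [
                {
                    "gene_id": a.gene_id,
                    **{f"n_{k}": v for k, v in a.counts.items()},
                    "endosperm_flag": a.endosperm_flag,
                }
                for a in annotations.values()
            ]
        )
        write_table(annot_df, outdir / "annot.tsv")
        with open(outdir / "report.json", "w") as handle:
            json.dump({"summary": summary, "metadata": metadata}, handle, indent=2)
        with open(outdir / "resolved_config.json", "w") as handle:
            json.dump(metadata["config"], handle, indent=2)
    return report
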