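# desatsig

Substrate-specificity prediction for plant acyl-ACP Δ9 desaturases, with the
quantitative stages needed to connect a prediction to seed-tissue evidence.

## The problem

Soluble plastidial acyl-ACP Δ9 desaturases insert the first *cis* double bond
into a saturated acyl chain. The archetype of the family (stearoyl-ACP
desaturase, SAD) prefers 18:0-ACP and makes oleic acid (18:1Δ9, an ω-9
monoene); divergent family members prefer 16:0-ACP and make palmitoleic acid
(16:1Δ9, an ω-7 monoene) — a high-value fatty acid that some seeds accumulate
specifically in the developing endosperm. Which family members are the
16:0-ACP–specific endosperm enzymes is decided, to a first approximation, by
eight residues lining the lower substrate-binding channel: M114, L115, T117,
L118, P179, T181, G188 and F189 in the numbering of the castor archetype
RcSAD1. An enzyme whose eight residues match the archetype is predicted
18:0-specific; divergence marks a 16:0-specific (ω-7) candidate, and candidacy
for the endosperm role additionally requires endosperm-expression cis-elements
(skn-1, core `GTCAT`; GCN4, core `TGAGTCA`) in the gene's 2-kb promoter.

`desatsig` implements this analysis as a tested pipeline for family-scale
protein sets, plus the downstream quantification used to corroborate a
candidate: qPCR relative expression by 2^−ΔΔCq with two reference genes,
GC-FAME composition (percent of total fatty acids, C17:0 internal standard),
and the Pearson/OLS association between a gene's expression and a fatty-acid
species across tissue samples.

## Pipeline

1. **domain scan** — position-specific scoring matrix over a conserved block
   of five characterized reference enzymes; triage gate for family membership.
2. **pocket mapping** — global Needleman–Wunsch alignment (BLOSUM62, affine
   gaps 10/1) of each candidate to RcSAD1; the eight pocket positions are
   transferred through the alignment and read off as the *pocket signature*.
3. **classification** — archetype rule: all eight residues within the allowed
   sets ({M},{L,I},{T},{L},{P},{T},{G},{F}) → `omega9`; any divergence →
   `omega7_candidate`; gapped pocket column → `unresolved`.
4. **cis-element filter** — exact-core scan of promoters on both strands;
   final endosperm candidates are ω-7 candidates with at least one skn-1 or
   GCN4 occurrence.

A synthetic-data module generates families, promoters and quantitative panels
with planted ground truth so every stage is testable without external data.

## Worked example

```
$ desatsig simulate promoters --seed 7 --outdir prom
17 promoters -> prom
$ desatsig run --proteins src/desatsig/data/ghsad_family.synthetic.faa \
      --promoters prom/promoters.fa --outdir out
{"n_proteins": 17, "n_domain_positive": 17, "omega9": 10,
 "omega7_candidate": 7, "unresolved": 0, "n_final_candidates": 6,
 "final_candidates": ["GhA-SAD5", "GhA-SAD6", "GhA-SAD7",
                      "GhD-SAD5", "GhD-SAD7", "GhD-SAD8"]}
```

All 17 cotton family members pass the domain gate; ten carry the intact
archetype pocket (predicted ω-9/18:0-specific), seven diverge (ω-7
candidates), and six of those carry endosperm cis-elements — GhD-SAD4 drops
out because its promoter has neither element. `out/` contains the per-protein
calls (`calls.tsv`), the extracted signatures (`signatures.tsv`), motif hits
in BED6 + ATG-offset form (`hits.bed`), promoter annotations (`annot.tsv`)
and a JSON report with the resolved configuration and its digest.

The quantitative stages chain the same way:

```
$ desatsig simulate panel --seed 7 --outdir panel
$ desatsig expression --cq panel/cq.tsv --calibrator embryo_15DAF_r1 --out rq.tsv
$ desatsig fame --peaks panel/peaks.tsv --out profile.tsv
$ desatsig associate --expression rq.tsv --fatty-acids profile.tsv \
      --pairs GhA-SAD6:16:1 --out assoc.tsv
```

`assoc.tsv` then reports the Pearson r, OLS slope/intercept, n and p-value of
palmitoleate content on the gene's relative expression (about r ≈ 0.85 over
the 24 endosperm samples of the default panel design).

## Layout

- `src/desatsig/` — library modules (`seq_io`, `domain_scan`, `pocket_map`,
  `specificity`, `cis_scan`, `expression_quant`, `fame_quant`, `association`,
  `synthetic_data`, `pipeline`, `cli`).
- `src/desatsig/data/` — the transcribed pocket-residue table, archetype
  profile, FAME molar masses, and synthetic scaffold sequences (the study
  deposited no sequence records; files are marked `*.synthetic.*`).
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
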