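# Methods

## Pocket-residue model of substrate specificity

The acyl-ACP Δ9 desaturase family shares a common fold in which eight residues
line the lower portion of the hydrophobic substrate channel. In RcSAD1
numbering these are positions 114, 115, 117, 118, 179, 181, 188 and 189, with
archetype residues M, L, T, L, P, T, G, F. Deep channels built by the
archetype set accommodate 18:0-ACP; substitutions that shorten or reshape the
channel shift preference toward 16:0-ACP. The package's working model is the
binary rule observed in the characterized panel: enzymes carrying the intact
archetype set are 18:0-specific (ω-9 producing), any divergence marks a
16:0-specific (ω-7) candidate. The rule is deliberately *not* a
nearest-neighbour classifier over the reference panel: confirmed ω-7 enzymes
can differ from each other at more of the eight positions than they differ
from the archetype (the two confirmed cotton endosperm enzymes share only 5/8
pocket residues), so distance to a reference is not a reliable class signal,
whereas "identical to the archetype or not" reproduces the characterized
panel exactly.

Position 115 admits both L and I in the default archetype profile: three
family members carry I there while grouping with the archetype in every other
respect. A strict-identity profile (`ArchetypeProfile.strict()`) is available
for sensitivity analysis. Classification outcomes are `omega9`,
`omega7_candidate` and `unresolved`; the last is reserved for signatures with
a gapped pocket column and is never silently coerced.

## Numbering transfer by global alignment

Pocket positions are defined on RcSAD1 and transferred to each query through
an optimal global alignment (Gotoh three-state dynamic program): BLOSUM62
substitution scores, gap open 10, gap extend 1, a gap of length L costing
`open + (L-1)·extend`. Family members are full-length homologs, which makes
global alignment the appropriate numbering-transfer tool; local modes are out
of scope. Traceback ties are broken deterministically (diagonal over up over
left), so repeated runs give byte-identical signatures. If the query has a
gap in a pocket column the signature records a GAP marker — a residue is
never invented — and classification returns `unresolved`. The implementation
is validated against exhaustive enumeration of all alignments for peptides of
length ≤ 6 and against an independent aligner (biotite `align_optimal`) on
longer random sequences.

## Domain triage

Family membership is gated by a position-specific scoring matrix built from
an ungapped 81-column block of the five reference sequences (columns are
log2-odds of residue frequency with pseudocount 0.5 against the uniform 1/20
background, i.e. bit scores). A PSSM, not a profile HMM, is used on purpose:
the gate only needs desk-scale triage, and the alignment stage downstream
absorbs indels. The positive threshold is frozen in the packaged block file
at half the profile's consensus score — a structural midpoint at which every
packaged reference scores positive and shuffled versions score far below.
Because the PSSM is ungapped, an indel falling inside the scored window can
push a true family member below threshold; the pipeline treats the gate as a
coarse filter, and the property suites therefore score signature recovery on
alignment output rather than on gate output.

## Cis-element filter

Promoters (nominally the 2-kb region upstream of ATG; longer input draws a
warning, not an error) are scanned for exact occurrences of the skn-1 core
`GTCAT` and GCN4 core `TGAGTCA` on both strands; reverse-strand hits are
reported in forward BED coordinates (0-based half-open) with an additional
ATG-relative offset column (−1 = base immediately upstream). Overlapping
occurrences all count; `N` matches nothing. The endosperm flag is an OR over
the two elements, and the final candidate set is the intersection of the
ω-7 candidates with flagged promoters. A missing promoter record leaves a
gene classified but not finally called (`promoter_missing`): sequence
divergence and promoter content are independent lines of evidence, so absence
of data is not treated as absence of the element. Exact-core matching (no
IUPAC degeneracy, no weight matrices) reflects that only core sequences are
defined for these elements here.

## qPCR quantification (2^−ΔΔCq)

Technical replicates are averaged on the Cq scale; the per-sample reference
aggregate is the arithmetic mean of the two reference genes' mean Cq (the
geometric mean of their quantities — the standard multi-reference
combination). ΔCq = target − aggregate, ΔΔCq subtracts the calibrator
sample's ΔCq, relative quantity = 2^−ΔΔCq. The calibrator must be named
explicitly; there is no silent default, and all outputs are
calibrator-relative. Replicate dispersion is reported as the Cq standard
deviation but not propagated into the fold values. Amplification-efficiency
correction and statistical testing of expression differences are out of
scope. Adding any constant to every Cq leaves all fold values invariant, and
swapping the reference genes changes nothing; both are tested.

## GC-FAME composition

Peak areas per species are normalized within sample to percent of total
fatty acids with the C17:0 internal standard excluded from the total. The
default mode is plain area normalization; a molar mode divides areas by the
packaged methyl-ester molar masses first (the two agree exactly when masses
are equal). Whether published Mol% values carry a molar-mass correction is
generally ambiguous, so both modes are exposed and the choice is recorded in
pipeline provenance. When the added mass of internal standard is known,
absolute micrograms per species are computed as `area / istd_area ×
istd_mass`. Per-sample compositions sum to 100 to within 1e−9 relative
tolerance by construction; peak calling and retention-time assignment are
upstream of this package.

## Expression–lipid association

For each requested (gene, species) pair, samples are joined by exact key
(replicate-level by default, with the aggregation mode recorded in the
output), and the paired series is summarized by the Pearson correlation, the
OLS fit of composition on expression, and the two-sided t-test of r = 0 with
n−2 degrees of freedom. Pearson correlation matches the linear-regression
framing of the endosperm question; rank correlation is not offered. Zero
variance or fewer than three pairs raises a typed error rather than
propagating NaN.

## Synthetic-data generators

All generators require an explicit integer seed and drive a single
`numpy.random.default_rng`; equal seeds give byte-identical outputs.

**Families** derive from the packaged archetype scaffold. Omega-9 genes draw
pocket residues from the allowed sets; omega-7 genes receive one to four
divergent residues drawn from the divergence repertoire observed in
characterized ω-7 enzymes (position 115 never diverges). Background
substitutions (rate 0.02 by default) and indels avoid the pocket columns —
indels additionally keep a ±2-residue margin so the true pocket coordinates
remain well defined under alignment — and the truth table records planted
class, letters and post-indel positions. Non-family entries are full shuffles
of the scaffold and fail the domain gate.

**Promoters** are sampled at 35% GC (AT-rich, as plant promoters are), then
scrubbed so no motif core occurs on either strand anywhere outside the
planted spans; requested occurrences are inserted at recorded non-overlapping
positions (8-bp minimum separation) with random strand. Junction artifacts
are re-scrubbed, so scanner counts equal planted counts exactly — which is
what makes exact-recovery testing meaningful.

**Quantitative panels** emulate a dissected developing-seed experiment:
embryo and endosperm at 15/25/35/45 days after flowering, six biological
replicates per tissue/stage (24 endosperm samples, matching the replication
of the motivating design), qPCR in technical triplicate with Cq noise sd 0.2
cycles, biological log2-variability 0.25, and two stable reference genes. The
endosperm 16:1 percentage is `baseline + coupling × expression + noise`
(baseline 5 Mol%, coupling 0.9 Mol% per fold unit, noise sd 1.7 Mol%,
redrawn in the rare case the value would leave (0.5, 99) so compositions stay
valid); remaining species are rescaled to keep the total at 100. These
defaults place the peak endosperm palmitoleate near 15 Mol% and the
asymptotic expression–16:1 correlation near 0.85, the regime reported for
developing cotton endosperm. Peak areas are back-computed from composition
with a random per-sample injection scale, so area-mode normalization
recovers the true composition exactly.

What the generators do *not* emulate: real sequence evolution (no
substitution-rate structure, no codon model), promoter element grammar beyond
presence/absence of two cores, amplification-efficiency differences between
genes, chromatographic peak-shape effects, or compositional covariance
between fatty-acid species beyond the closure constraint. Passing the
recovery suites therefore demonstrates correctness of the computations on
data satisfying the model assumptions, not robustness to every way real data
violate them.

## Problem sizes and numerical choices

The recovery suites run at desk scale: 100 seeded six-member families with
three indels each for signature recovery, 100 seeded promoters for motif
recovery, and 200 seeded 24-sample panels for correlation recovery, whose
estimates are checked against the generator's asymptotic correlation
(measured once on a 1600-sample panel) with 95% Fisher-z bands and a ≥90%
coverage requirement — conservative for the mildly non-normal panel design.
Alignment DP uses 64-bit integer scores (BLOSUM62 and the gap penalties are
integers), making tie detection exact. Composition sums are validated at
1e−9 relative tolerance. Degenerate inputs (empty sequences, constant
series, zero internal-standard area, gapped pockets) raise typed errors from
a small exception hierarchy rather than returning sentinel values.

## Known limitations

- The pocket rule is a sequence-level surrogate; it cannot resolve enzymes
  whose specificity is set outside the eight positions, and the confirmed
  false positives of the rule (archetype-divergent enzymes that nonetheless
  prefer 18:0-ACP) show its candidate lists need functional follow-up.
- The packaged scaffold sequences are synthetic stand-ins carrying the
  transcribed pocket letters at offset-consistent coordinates; they reproduce
  the published residue table through the full pipeline but are not the real
  proteins, and alignment behaviour on real family sequences (paralog
  divergence, transit peptides) may differ.
- The domain gate is indel-sensitive by design (ungapped PSSM).
- Printed residue indices in the transcribed table are internally
  inconsistent for a few entries; the package treats letters as authoritative
  and derives numbering offsets as the per-column mode.
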