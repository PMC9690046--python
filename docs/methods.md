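# Methods

## Coordinate system and reference

All coordinates are 1-based and inclusive on the rCRS (NC_012920), matching
m.-style nomenclature. The mitochondrial chromosome is circular; the control
region (16024..576) is the only annotated interval that spans the origin and
is represented as a single interval with an explicit `wraps_origin` flag, so
the region list maps one-to-one onto the regions a report names. BED export
converts to 0-based half-open coordinates and splits wrapping intervals in
two.

The packaged reference (`src/mitovar/data/synthetic_rcrs.fa`) is a
deterministic synthetic stand-in for the rCRS, regenerable via
`reference.write_synthetic_reference`: uniform-random A/C/G/T of the exact
rCRS length, overwritten with (a) the D310 context — A A at 301–302, C₇ at
303–309, T at 310, C₅ at 311–315, G C T at 316–318 — and (b) the canonical
reference allele at every position named by the variants this package
discusses (backbone sites such as 263/750/1438/4769/8860/15326, association
sites such as 10398/16183/16189/16311/16519, the MDP-window sites, and the
fixture sites 2145/2146/2275/3480/8601/16147). Every coordinate-dependent
computation is reference-file-agnostic; supplying a genuine NC_012920 FASTA
changes nothing but the sequence. What the stand-in does **not** emulate is
the rCRS's real base composition and repeat structure outside those pinned
windows, so absolute alignment identities and pairwise-difference counts on
synthetic cohorts say nothing about real GenBank data; the coordinate
logic, normalization, typing, filtering and statistics are exercised
identically.

Known coordinate quirks are kept as published and are overridable through
the region table: SHLP5 defaults to 2780–2854 (the span its report column
uses) rather than the 2485–2559 listed in the methods text, which duplicates
SHLP1; position 16519 lies in the control region but **outside** HVR1
(16024–16383), and the annotation follows the coordinates, not any table's
row grouping. The reference carries A at 3010 so that the MDP-table
spelling m.3010A>G is a genuine A>G change.

## Alignment

Samples ≥ 15,400 nt are aligned globally, shorter ones semi-globally (free
end gaps on the reference) so fragments locate their own window; the
footprint (covered reference interval) feeds the coverage-aware
denominators. Alignment is minimal-edit (edlib) bounded by a maximum edit
distance that starts at 200 and doubles on overflow up to five times —
functionally a banded alignment; human mitogenome divergence is a few dozen
edits, so the first band almost always suffices. Unit edit costs directly
implement the minimal-edit parsimony this pipeline wants at homopolymers (a
substitution is one edit and always beats a deletion-plus-insertion pair),
which is why no affine gap scoring is exposed. Sequences whose aligned
identity falls below 0.90 (configurable) are rejected as unalignable;
IUPAC ambiguity codes match any component base during alignment. Samples
are assumed linearized at the rCRS origin, the convention of deposited
GenBank mitogenomes; origin-spanning inputs fail with a clear error.

## Variant normalization

Raw differences (mismatch columns; maximal gap runs; mixed runs merged into
delins candidates) are normalized HGVS-style: common affixes trimmed,
deletions and insertions shifted to their 3′-most equivalent placement, an
insertion equal to the immediately preceding reference run emitted as a
duplication, and replacement events as minimal-span delins. Normalization
is idempotent, and re-applying a normalized variant reproduces the edited
sequence exactly (both are property-tested). This rule is what makes a C
inserted anywhere in the 311–315 run `m.315dup` and anywhere in 303–309
`m.309dup`. VCF output left-pads indels with the anchor base per the VCF
spec while keeping the 3′-shifted placement.

## D310 typing

The typing window is 302–318 — one anchor base either side of the tract —
because 3′-shifting can move indel anchors to the run ends. The observed
tract string (sample bases aligned to 303–315 plus insertions anchored
after 302–315) is matched exactly against each candidate allele applied to
the reference tract C₇TC₅; the seven candidate strings are pairwise
distinct, so classification is unambiguous, and anything unmatched is
`other` (the tract is genuinely polymorphic, so `other` is a category, not
an error). Heteroplasmic bases in the window force `other` with a remark
since tract length is then undefined.

Calling and typing are reconciled: when the tract matches a named allele,
the normalized variants lying wholly inside the window are replaced by that
allele's canonical label. This matters for `m.310delinsCCTC`, whose
minimal edit script is three separate C insertions (C₇TC₅ → C₉TC₆), and
keeps one sample from ever carrying both `m.310del` and `m.315dup`
(structurally impossible: one category per sample).

## Phantom screening

Scores come from an input panel (two-column TSV: label, occurrence count)
because the published scoring panels compiled from thousands of complete
mitogenomes are not redistributable. Rule: score ≥ 3 → common; score < 3
with ≥ 2 cohort carriers → rare, retained and flagged; otherwise phantom
candidate, excluded from association (policy `exclude`) or only reported
(policy `report-only`). Without a panel the cohort's own carrier counts
stand in as scores, loudly logged, which degrades the rule to pure
recurrence. The six backbone labels are whitelisted from exclusion by
default, mirroring the retention of haplogroup-defining polymorphisms. An
implanted true variant with a single carrier is indistinguishable from an
artifact under this rule and is excluded — by design; the guarantees are
100% artifact sensitivity and zero exclusion of labels with ≥ 2 carriers.

## Statistics

Uncorrected Pearson chi-square on the 2×2 carrier table, 1 df, upper-tail
p, α = 0.05. No continuity correction: the uncorrected statistic reproduces
all twelve reproducible published p-values within ±0.002, while the
Yates-corrected one does not (e.g. 27/78 vs 21/34 gives p = 0.0076
uncorrected, ≈ 0.013 corrected, against a printed 0.007). Two published
p-values (m.16519T>C 0.007 and m.2706A>G 0.418) are inconsistent with
their own printed counts (which give ≈ 0.49 and ≈ 0.15 respectively) and
are excluded from reproduction. No multiple-testing correction is applied
to significance flags, matching the original analysis; a Bonferroni-adjusted
α column is emitted for transparency. Degenerate tables (a zero margin)
yield "-" rather than a number.

Carrier denominators are coverage-derived — a sample counts for a variant
only if its footprint covers the variant's full span and no span position
is censored (heteroplasmic or N in that sample) — because the original
analysis never states its denominator rule and its printed denominators
(78/90/66/50) cannot be reconciled exactly with its stated sequence
counts. Reproduction of printed tables therefore bypasses calling entirely
and feeds printed counts to the same chi-square (`table-stats`).

`population_diffs` operates on the substitution allele per site over the
region jointly callable by every sample; indels are length changes rather
than site alleles and are excluded, and sites heteroplasmic in any sample
are dropped. On substitution-only cohorts the mean pairwise difference
equals the brute-force Hamming distance between raw sequences (tested).

## Synthetic cohorts

Defaults of `study_mirror_spec` emulate the study conditions: 78 cases and
34 controls; the recurrent-variant carrier probabilities taken from the
published carrier fractions (m.10398A>G 9/50 vs 10/34, m.16183A>C 10/78 vs
5/34, m.16189T>C 17/90 vs 9/34, m.16311T>C 11/90 vs 8/34, m.16519T>C 34/66
vs 20/34); the D310 allele mix from the published per-allele fractions
(cases 27:4:1:47 of 78 for m.310del : m.310T>C : m.310delinsCCTC :
m.315dup, controls 21:0:1:13 of 34) — each group's fractions sum slightly
above 1 because the printed denominators overlap, so the mix is
renormalized by its own sum (78/79 and 34/35), leaving essentially no
reference-tract mass, consistent with D310 variation being reported in ~98%
of sequences; the six-variant backbone at probability 0.98 per variant
("more than 98% of the analyzed sequences"); ~2 private singletons per
sequence (the reported unique-polymorphism load per sequence); a 0.2
heteroplasmy probability (≈ 22 heteroplasmic sites in 86 complete
sequences, order-of-magnitude); seven single-carrier artifact sites (seven
phantom polymorphisms were reported); and 30% fragments, split 1:2 between
HVR1 and HVR2 (12 vs 24 partial sequences). Singletons and heteroplasmies
are re-drawn away from implanted spans and a ±6 nt buffer around the D310
window, with D310 edits taking priority; phantom conflicts are skipped and
logged, never silently corrupted. Fragments are emitted linearized; truth
records are filtered to the fragment's window so they state exactly what a
caller can see.

What the generator does **not** emulate: haplogroup phylogenetic structure
beyond the backbone (carriers are drawn independently per variant),
mutation-rate heterogeneity along the genome, sequencing error beyond the
explicit artifact sites, and length variation of the 16184–16193 poly-C
(the 16189 context) — so passing tests demonstrate correctness of the
pipeline's logic under realistic variant loads, not performance on real
GenBank submissions.

## Problem sizes and runtime choices

The test suite and acceptance script size their simulations to run in
seconds per stage on one CPU: exact-recovery on one full-size 112-sample
cohort (alignment of a complete mitogenome takes ~10 ms); D310 oracle
equivalence over all 64 tract shapes; chi-square calibration on 1,000
random tables against the closed-form erfc oracle plus 500 null cohorts of
50 + 50 samples at carrier frequency 0.3 (null calibration uses the
generator's truth stream directly — the carrier table is a sufficient
statistic of a simulated cohort, and alignment is already exercised by the
recovery check); and carrier-frequency recovery over 200 replicate truth
streams. The whole suite runs in ~10 s, the acceptance script in ~8 s.

## Known limitations

* Origin-spanning sample linearization is not handled (fails explicitly).
* The synthetic reference preserves named-site contexts only; results on
  it do not transfer quantitatively to the real rCRS sequence.
* Heteroplasmy handling assumes consensus-style IUPAC encoding; read-level
  or frequency-resolved heteroplasmy is out of scope.
* `population_diffs` ignores indel alleles.
* No haplogroup assignment, phylogenetic reconstruction, or NUMT
  screening.
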