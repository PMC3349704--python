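# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the underlying
description is qualitative, and what the synthetic fixtures do and do not
establish.

## Box detection and C/D layouts

Boxes are detected by Hamming distance against IUPAC consensus patterns
(C = `UGAUGA`, D = `CUGA`, H = `ANANNA`, ACA = `ACA`; `N` matches any
base). "Intact" is nowhere quantified in the literature this package
operationalizes, so tolerances are explicit defaults, all configurable:

| box | pattern | default max mismatches | rationale |
| --- | --- | --- | --- |
| C | UGAUGA | 1 | tolerates the known RUGAUGA variation |
| D | CUGA | 0 | shortest, most constrained box |
| C' | UGAUGA | 2 | internal copies are often imperfect |
| D' | CUGA | 1 | same |
| H | ANANNA | 0 | three fixed positions only |
| ACA | ACA | 0 | — |

A C/D layout is scanned over a candidate-scale sequence (50–120 nt by
default): a C hit must start within 12 nt of the 5' end, a D hit must end
within 12 nt of the 3' end, and every such (C, D) pairing is reported
(deduplicated on the pair of start positions). Genome-scale input reaches
this scanner through homolog-search hit windows, mirroring how such
searches are actually conducted. Internal C'/D' copies are attached when
found between the outer boxes, preserving the 5'-C…D'…C'…D-3' order; C' is
chosen first (fewest mismatches, then closest to D), D' restricted
upstream of it. This tie-break is a convention, not biology; both boxes
carry their mismatch counts in the output so callers can re-judge.

The terminal stem ("short inverted repeats") is the longest ungapped
antiparallel pairing — Watson–Crick plus at most one G-U by default —
between an 8-nt window ending at the C box and an 8-nt window starting
after the D box, reported when at least 4 bp pair; ties break toward the
most terminal pairing. No thermodynamics are computed: a deterministic
pairing rule keeps the check reproducible and configurable, at the price
of ignoring stem energetics.

H/ACA support is deliberately minimal: an H-box hit in the interior third
of the sequence plus an ACA ending exactly `aca_offset` (default 3) nt
from the 3' end. Hairpin structure and pseudouridylation pockets are out
of scope.

## Guide duplexes and the four-nucleotide rule

The guide (antisense element) region is the window of up to 20 nt ending
immediately 5' of the D or D' box, clipped at the preceding box. Duplexes
against supplied target RNAs are ungapped, antiparallel, every position
Watson–Crick or G-U (G-U counts toward element length; up to 3 G-U by
default; internal mismatches disallowed by default, configurable to 1),
with length in [9, 20] nt. All maximal such pairings are enumerated per
anti-diagonal; a window never starts or ends on a mismatch.

Site prediction: for a duplex supported by the box's guide region, the
guide partner of the methylated nucleotide is the candidate position at
box start − 5 — exactly four candidate nucleotides strictly between it
and the first box nucleotide. The counting convention is stated here
precisely because prose statements of the rule ("four nucleotides from
the box") are ambiguous; this choice makes the standard guide rule and
the constructions in the synthetic module coincide, and every emitted
prediction is asserted against it. Whether a G-U pair may sit opposite
the methylated nucleotide is left permissive by default.

Claimed-target validation re-derives the geometry from the claim and
emits machine-readable violations: `ELEMENT_IS_INTERBOX_SPAN` (the claim
is a whole C–D'/C'–D/C–D fragment rather than a specific complementary
element), `DUPLEX_TOO_SHORT`, `SITE_UNPAIRED`, `ELEMENT_NOT_ADJACENT`,
`OFFSET_GT4` (the claimed site's guide partner is more than four
nucleotides from the nearest downstream D/D' box), and
`TARGET_DISALLOWED` for targets on a configurable list that ships with 5S
rRNA only, since eukaryotic 5S rRNA carries no 2'-O-methylated
nucleotides.

## Genomic context

Internally all coordinates are 0-based half-open; GFF3 (1-based
inclusive) and BED are converted at the file boundary. Multi-transcript
genes collapse to the transcript with the greatest summed exon length
(ties: lexicographically smallest transcript id). "Intronic" means fully
contained in a single intron — a snoRNA must survive intron processing —
while any ≥1-nt exon overlap is `exonic_overlap` (checked first when
annotations overlap), and everything else is intergenic. With overlapping
host genes the shortest containing intron wins, ties by gene id. Intron
ordinals follow gene orientation. Transcript evidence (mRNA/EST
intervals) counts only on full containment.

## Homolog search

The seeded local aligner favors sensitivity over statistics, echoing a
high-sensitivity word-seeded search with word size 3 and a first-gap cost
of 1. Every exact word match seeds a cheap ungapped X-drop walk along its
diagonal; the best segment found (the HSP, located by a maximum-subarray
pass over the walked range) triggers the gapped stage when it scores at
least `gapped_trigger` (11; capped at `min_score`). The gapped stage is a
banded local Smith–Waterman (affine gaps: a k-gap costs
`gap_open + (k−1)·gap_extend`) over the diagonals within
`xdrop / gap_extend` of the anchor, processed in descending HSP-score
order, with substitution steps through already-reported alignment paths
masked so one locus is not re-reported while distinct nearby copies still
surface. With word size 1 and an effectively unbounded X-drop the band is
unbounded and the procedure reduces to exhaustive local alignment — the
limit behavior the tests pin against an independent Smith–Waterman
implementation. Hits are raw-score thresholded (`min_score` 16, a
configuration decision, not a published value); no E-values are computed
because every hit is meant to be inspected by the downstream box, stem,
element and context checks rather than trusted on score.

Identity between homologs is computed on a global alignment with free end
gaps (match +1, mismatch −1, gap −2): matches over alignment columns,
excluding the terminal gap-containing runs from the denominator and
counting internal gap columns as non-matches. Among co-optimal alignments
the aligner's first optimum is used after orienting the arguments
canonically, which makes the value symmetric.

## Classification

A candidate is assigned to the family whose reference it most resembles;
assignment requires coverage identity — matched columns over the *full*
reference length — of at least 55%, the floor of the identity range
reported between vertebrate homologs. Coverage identity, not overlap
identity, is the gate because a short chance local alignment can look
~70% identical over its own span while covering half the reference;
truncated but genuine copies retain ~60% coverage and pass.

All sequence checks run through the global alignment to the family
reference, so specific reason codes emerge even when de novo scanning
fails: reference box windows are mapped through the alignment and
Hamming-checked against the consensus at classifier tolerances
(`BOX_MUT_C/D/DPRIME`; deleted consensus positions count as mismatches; a
box wholly inside a terminally-missing region is attributed to truncation
instead); the stem is re-sought around the mapped box positions
(`NO_STEM`); the family target site must be re-derivable from the mapped
guide regions (`ASE_DISRUPTED`; skipped for families without a recorded
target); and a candidate shorter than 90% of the reference
(`full_length_frac`) is flagged `TRUNC_5`/`TRUNC_3` according to which
end the alignment shows missing (the end with the larger unaligned
reference run; both when equal).

Context reasons apply unless the family is promoter-exempt:
`EXONIC_OVERLAP`, `ANTISENSE_STRAND` (intron processing requires sense
orientation), `INTERGENIC`. The verdict is `gene` iff no reasons;
`uncertain` only on the intact-but-intergenic path without transcript
evidence (reasons `INTERGENIC, NO_TRANSCRIPT_EVIDENCE`) — sequence-intact
intergenic copies *with* containing transcript evidence are upgraded to
gene with a provenance note; everything else is `pseudogene`. The census
separates gene / pseudogene / uncertain counts per family and species.

## Nomenclature

Prefix = lowercase first letter of the genus plus the first three epithet
letters (`Mus musculus` → `mmus`); on collision the epithet is extended
letter by letter (`Microcebus murinus` with `mmus` reserved → `mmur`,
then `mmuri`, …). The extension rule is this package's own convention —
only the four-letter examples and the need for distinctness are given in
the literature — and epithets shorter than three letters are padded from
the genus with a warning.

## Synthetic fixtures

The generator emulates the canonical gene anatomy: 6-nt stem arm, C box,
8-nt spacer, D', 6-nt spacer, C', a 3-nt spacer, the antisense element
(reverse complement of the target window placed so the four-nucleotide
rule lands exactly on the family's target position), D box, complementary
3' arm — 61 nt with the default 12-nt element. The 3-nt spacer between C'
and the element keeps a legitimate element claim distinguishable from a
whole-inter-box-span claim. Every construct is validated against the
package's own scanners (exactly one layout, all four boxes, a stem, the
designed element recovering the designed site) and resampled otherwise;
pseudogenization modes (box substitutions beyond tolerance, 40% terminal
truncations, destructive element shuffles, intact intergenic retro
copies) are validated the same way. Toy genomes place gene copies ≥50 nt
inside host-gene introns (hosts alternate strand across families) and
pseudogene copies in intergenic space, and the random background of each
contig is resampled until no family reference aligns to it above the
search threshold outside the implants — the truth table must be the
complete list of snoRNA-similar loci for truth-recovery runs to be
meaningful. All randomness flows from a single seed through fixed
per-purpose streams; fixture files are byte-stable.

What passing on fixtures does not show: the generator produces uniform
base composition, exact or cleanly degraded copies, single-intron-chain
hosts and small genomes. Real genomes have composition bias, deep
homolog divergence (down to ~55% identity, where a score-16 cutoff on a
±1 scheme will miss true homologs), fragmented assemblies, overlapping
and mis-annotated gene models, and pseudogenes degraded in several ways
at once. Results on fixtures validate the logic, not genome-scale recall.

## Problem sizes and numerics

Default toy studies use 3 families × (1 gene + 5 pseudogene-mode copies)
on ~4-kb contigs with 400-nt introns and a 400-nt target RNA — sizes
chosen so a full simulate → classify cycle completes in about a second
while every code path (all pseudogene classes, both strands, all location
calls) is exercised. Scores are small integers throughout; the only
floating-point quantities are identities. Ties are broken
deterministically everywhere (documented per operation), degenerate
inputs (empty files, single-exon genes, unknown contigs, windows out of
range) raise typed errors or defined fallbacks, and identical inputs with
identical seeds give byte-identical outputs.

## Known limitations

No E-value statistics; no covariance-model or profile detection; no
thermodynamic folding (the stem finder is combinatorial); H/ACA targets
and hairpins unhandled; no promoter prediction — intergenic calls lean on
transcript evidence and the promoter-exempt list; the classifier's
tolerances are conventions exposed as configuration, and reports carry
the raw evidence so users can re-threshold without re-running.
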