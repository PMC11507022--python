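# Methods

## Canonical frame and reference panel

All positional statements (e.g. "position 12") refer to a fixed
109-position canonical frame anchored on the bundled pvalb4 exemplar,
the family whose structure historically defined parvalbumin numbering.
Position 109 may be unoccupied — many real parvalbumins are one residue
shorter. A query is placed in the frame by global pairwise alignment
(BLOSUM62, gap open 10, gap extend 1, end gaps free) against each
per-family consensus; the best-scoring profile provides the coordinate
assignment, ties going to the lexicographically first family. Insertions
relative to the frame are recorded but carry no canonical number, so the
numbering of the 109 ancestral positions is stable. Queries covering
less than 50 % of the frame are rejected as not alignable as
parvalbumin; because validated sequences are 90–130 residues and the
aligner is semi-global, this guard only fires on pathological inputs.

The bundled reference panel is **synthetic by construction**: the
package redistributes no database record. A 109-residue
parvalbumin-shaped scaffold is modified by explicit substitution tables
to reproduce the documented *group structure* of teleost parvalbumins:

* three lineages (Alpha, Oncomodulin, Beta-2) separated by 27
  lineage-specific positions (~60–64 % cross-lineage identity, close to
  the real range);
* ten families with realistic relative distances: pvalb1–4 are mutually
  ~86–88 % identical, pvalb5/pvalb10 ~83 % to them, while pvalb6 vs
  pvalb7 and pvalb8 vs pvalb9 differ at only three positions (~97 %) so
  that sequence alone cannot separate them — mirroring the real pairs
  that only chromosomal context resolves;
* the field's diagnostic residues planted at canonical positions 12, 16
  and 19 (pvalb2: A12 + small 19; pvalb3: T12 + Q19; pvalb4: D/E 16 +
  K19);
* the four ohnologous regions as chromosome metadata: pvalb8-4-1-5 on
  Chr.A, pvalb9-2-3-10 on Chr.B, pvalb6 on Chr.C, pvalb7 on Chr.D.

Each family contributes three entries (consensus plus two variants with
three neutral substitutions each, at positions owned by no rule), so
per-family frequency profiles are non-trivial while diagnostic columns
stay clean. One entry is 108 residues long, exercising the unoccupied
position 109. Consequently, every quantitative claim validated on this
panel is a claim about the *procedure* under a faithful group structure,
not about any real species' sequences; with real data the same code path
applies unchanged via `load_reference_panel`.

## Percent identity

Identity = matches / aligned residue pairs (columns where both
sequences carry residues), after global alignment with the parameters
above. End gaps are free so that 108- vs 109-residue pairs are not
penalized for the missing terminal position. `X` (undetermined) never
counts as a match and never satisfies a diagnostic rule. On
equal-length, gap-free pairs this definition coincides with the
Hamming-based value, which the test suite uses as a brute-force oracle.

## Diagnostic rules

Rule discovery operates on the mapped panel grouped by family or
lineage. At each canonical position, a group's *majority set* is the
smallest residue set covering ≥ 80 % of its members (gaps and X
excluded); a rule is emitted when that set is disjoint from every
residue observed in any other group at the position. The 80 % threshold
and the strict-disjointness requirement are conservative choices that
favor precision over rule count; groups with fewer than two members are
excluded with a warning. All rule weights default to 1. The "small"
residue class used for the pvalb2 position-19 rule is fixed as
{G, A, S, C, T} — the standard small-side-chain grouping. Scoring a
query against a rule group returns the weighted fraction of matched
rules; a gap at a rule position counts as a non-match.

## Lineage and family calls

Lineage is decided by nearest-reference identity with a ≥ 2-point
margin over the best entry of any other lineage (confidence =
margin/20, capped at 1); below that margin, lineage-level motif scores
decide. Family calls combine three evidence sources with precedence
synteny > motif > identity:

1. a chromosome label (compared on its alphabetic stem, so Chr.B2 from
   a duplicated region matches the ancestral Chr.B) restricts candidates
   to the families of that region; an unknown label falls back with a
   warning;
2. within Beta-2, candidates are first narrowed to pvalb1–4 vs pvalb5
   vs pvalb10 by identity, then diagnostic motifs rank the candidates;
3. identity ranking breaks remaining ties (requiring a ≥ 1-point gap,
   otherwise the tie is surfaced).

For the near-identical pairs pvalb6/7 and pvalb8/9 the caller refuses to
pick a member from sequence evidence alone and returns an explicit
`pvalbN/M unresolved` value — a first-class result, not an error.
Confidence is the weighted fraction of evidence concordant with the
final call (weights 3/2/1 for synteny/motif/identity); it is a reporting
device, deliberately simple, and monotone under accumulating mutations
by construction of the evidence set.

## Hybrid detection

Chimeric genes arising from intergenic recombination are detected by
sliding a 20-position window (step 1) along the canonical frame and
comparing the query to its two closest family consensuses. A window
votes for a family when it favors it by ≥ 5 identity points; votes are
compressed into segments, short segments (< 3 windows) are discarded as
noise, and a hybrid is declared only when exactly one switch remains.
The breakpoint is the midpoint between the last window of the first
segment and the first window of the second; two or more switches yield
a "complex mosaic" flag instead of a hybrid call. The suggested name
follows the gene's unique part, operationalized as the minority (shorter)
component, with the 5′ component preferred on ties. Defaults (window 20,
step 1, margin 5) recover planted breakpoints within ±window/2 on the
synthetic chimeras and produce no false positives on pure sequences at
92 % consensus identity.

## Translated-similarity locus finder

A deliberately small seed–extend–chain search, not a spliced aligner:
exact protein 5-mers of the family consensuses seed diagonal runs in all
six reading frames; runs are extended ungapped with an X-drop of 10 and
kept at a BLOSUM62 segment score ≥ 60; segments are chained per strand
and family in transcription order with a 10 kb genomic gap limit,
requiring protein coordinates to progress past the previous segment's
end (20 residues of overlap tolerated, since extension can overrun an
exon boundary). Among eligible chains a segment joins the genomically
closest, which keeps exons with their own gene in tandem arrays;
genomically overlapping chains of different families are resolved by
total chained score. A locus is intact only if its chained translation
covers ≥ 70 % of the canonical frame and contains no internal stop
(adjacent same-frame blocks are merged across ≤ 45 nt so an in-frame
stop codon between them is seen). Coordinates are 0-based half-open
internally and in the BED-like export; human-readable reports are
1-based inclusive. Splice-site models and external aligner binaries are
out of scope; the finder is validated by round-trip against the genome
simulator, not against real gene structures.

## Gene naming

Naming is a pure function of (family, chromosome label, coordinates,
pseudogene flag): several intact same-family loci on one chromosome get
tandem letters A, B, … in ascending coordinate order; a family on
several chromosomes gets chromosome suffixes; both can combine
(PVALB2A_(Chr.B1)); single-copy families keep the bare name;
pseudogenes are flagged Ψ and excluded from lettering. Gene symbols
render uppercase, protein names lowercase, and the dotted variant
suffix (pvalb2.01) renders only when variant digits are set. Rendered
names round-trip through the parser.

## Allergen codes

The code grammar is `[A-Z][a-z]{2,3} [a-z]{1,2} N.IIVV` with
isoallergen and variant digits in 01–99. Threshold semantics are read
strictly: identity > 90 % is variant-level, > 67 % and ≤ 90 % is
isoallergen-level, ≤ 67 % is below the isoallergen threshold — exactly
90 falls to isoallergen level, exactly 67 below. Identity for these
decisions uses the package-wide convention over full-length sequences.
A query relating below 67 % (e.g. an α-parvalbumin against a β2
catalog) is flagged for an expert/clinical decision rather than
auto-coded, since clinical grouping may still keep allergen number 1.
Proposed codes take the next free variant digits within the anchor's
isoallergen, or the next free isoallergen digits.

## Synthetic-data generators

All generators are pure functions of seed and parameters and emit truth
records sufficient to score downstream operations.

* **Family sequences**: the target consensus identity (default 90 %,
  plausible range 50–100 since parvalbumins share > 45 % identity) is
  realized exactly as (109 − m)/109 by planting m substitutions at
  uniformly chosen non-protected positions, with replacement residues
  drawn from a BLOSUM62-biased proposal (softmax of half-bit scores) so
  mutants stay parvalbumin-plausible. "Preserve diagnostics" protects
  positions 12/16/19 plus the family's private positions. A nested
  `mutation_series` never reverts a substitution, which is what makes
  confidence-monotonicity testable.
* **Genomes**: each intact gene is embedded as two exons split at a
  codon boundary (a simplification — real parvalbumin introns need not
  respect codon phase) around a random 200–2,000 nt intron, uniformly
  random synonymous codons, minus-strand cassettes reverse-complemented;
  pseudogenes are 5′ fragments (45–55 codons) with a central in-frame
  stop. Intergenic spacers are 1.5–4 kb of uniform random nucleotides —
  no repeats, no GC structure, no real intergenic content, so the
  zero-false-positive result on random sequence bounds only statistical,
  not biological, background. Two stock layouts mirror documented
  situations: a neoteleost-like genome (nine genes, pvalb2 lost) and a
  salmonid-like genome (extra WGD, 13 intact genes, pvalb2A/2B tandems
  on both duplicated regions, pvalb1 and pvalb10 pseudogene fragments).
* **Allergen catalogs**: isoallergen groups differ by disjoint blocks of
  12 substitutions (pairwise ~78 %, inside the 67–90 window), variants
  within a group by ≤ 4 (> 90 %); infeasible combinations raise.

## What passing tests do and do not show

Synthetic fixtures demonstrate that the decision procedure is correct
*given* the documented group structure: planted families are recovered,
ambiguous pairs stay ambiguous without synteny, planted breakpoints and
loci are found. They cannot show robustness to real-world complications
absent from the generators — alignment-shifting indels, species-specific
duplication histories not in the four-region model, sequencing errors,
or genuinely divergent lineages. The two tests that compare against
published cross-species identity values require public database records
the package does not redistribute and fail with an explanatory message
until those are supplied locally.

## Problem sizes and seeds

Stock analyses use 200 planted sequences for recovery rates, 50 + 50
for the hybrid screen, and ~50–70 kb genomes per layout — sizes at
which every rate reported by `scripts/acceptance.py` is reproducible in
seconds from a single `--seed`. All randomness flows through explicit
seeds; identical configuration yields byte-identical reports.
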