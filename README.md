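# pvalbid — gene identities and allergen names for fish parvalbumins

Parvalbumins — small (~108–109 aa) EF-hand Ca²⁺-buffer proteins — are the
major food allergens in fish meat. Every teleost carries several of them
(7–22 genes per species), all descended from **ten genes in the teleost
common ancestor** (*PVALB1*–*PVALB10*) spread over four ohnologous
chromosomal regions, and falling into three ancient lineages: **Alpha**
(pvalb6/7), **Oncomodulin** (pvalb8/9) and **Beta-2** (pvalb1–5, pvalb10).
WHO/IUIS allergen codes ("Gad m 1.0201") number allergens per species in
order of discovery, so equal codes in different species routinely denote
*different* genes. `pvalbid` mechanizes the gene-based view for allergen
researchers and genome annotators: it assigns a candidate parvalbumin
sequence to its lineage and ancestral gene family, names duplicated loci,
and handles the allergen-code arithmetic.

## The decision procedure

For a query sequence *q* mapped onto a fixed 109-position canonical frame:

1. **Lineage** — nearest-reference percent identity (global alignment,
   BLOSUM62, gap open 10 / extend 1, end gaps free; identity =
   matches / aligned residue pairs). If the top reference beats the best
   entry of every other lineage by ≥ 2 points, its lineage is called;
   otherwise lineage-level diagnostic motifs decide.
2. **Family** — evidence combined with precedence
   **synteny > diagnostic motif > identity ranking**:
   * chromosomal context restricts the candidate families to those of the
     query's ohnologous region;
   * diagnostic residues separate the hard Beta-2 families, e.g.
     `T12 + Q19 → pvalb3`, `A12 + small residue at 19 → pvalb2`,
     `(D/E)16 + K19 → pvalb4` (rules are *derived* from the labelled
     panel, not hard-coded);
   * identity ranking breaks remaining ties.
   pvalb6 vs pvalb7 and pvalb8 vs pvalb9 are essentially identical in
   sequence; without chromosomal context the call is an explicit
   `pvalb8/9 unresolved`, never a guess.
3. **Hybrids** — intergenic recombinants are detected by sliding-window
   identity against the two closest family consensuses (window 20,
   margin 5 points, single switch required); the gene is named after its
   unique (minority) part.

Allergen-code semantics follow the WHO/IUIS thresholds: sub-number digits
1–2 distinguish **isoallergens** (> 67 % but < 90 % identity), digits 3–4
**variants** (> 90 %). Gene naming distinguishes tandem duplicates by
letters (*PVALB2A*/*PVALB2B*), whole-genome-duplication copies by
chromosome suffixes (*PVALB4_(Chr.A3)*), and pseudogenes by Ψ.

The bundled reference panel is **synthetic** (see
`src/pvalbid/panel_synthetic.py` and `docs/methods.md`): it reproduces the
documented group structure of teleost parvalbumins — lineages, the ten
families, the diagnostic residues, the four-region chromosome layout —
without redistributing any database record.

## Worked example

```bash
pvalbid --out-dir out simulate sequences --per-family 1 --identity 92
pvalbid --out-dir out classify out/simulated.fasta --synteny out/synteny.tsv
```

`out/classification.tsv` then contains one row per query (excerpt):

```
query_id            lineage      family   confidence  hybrid
sim_pvalb3_t92_s0   Beta2        pvalb3   1.00        no
sim_pvalb7_t92_s0   Alpha        pvalb7   1.00        no
sim_pvalb8_t92_s0   Oncomodulin  pvalb8   1.00        no
```

Each call carries its evidence trail, e.g. for `sim_pvalb3_t92_s0`:
`[synteny] chromosome Chr.B carries pvalb10/pvalb2/pvalb3 in the
reference layout; [motif] diagnostic residues best match pvalb3
(score 1.00); [identity] highest identity to pvalb3_syn_a (91.7%,
family pvalb3)`.
Without the `--synteny` table the same pvalb8 query returns
`pvalb8/9 unresolved` — sequence alone cannot separate that pair.

Allergen-code utilities:

```bash
$ pvalbid allergen parse "Gad m 1.0201"
species_abbrev   Gad m
allergen_number  1
isoallergen      02
variant          01
```

The numbered scripts under `analysis/` run the package's larger
narratives (panel identity structure, rule discovery, planted-fixture
classification, genome scan + gene naming, hybrid screen, allergen-code
checks) and write their tables under `results/`. For example
`python analysis/04_genome_scan_and_name.py` simulates a neoteleost-like
genome (nine parvalbumin genes) and a salmonid-like genome (13 intact
genes, a pvalb2A/2B tandem on both duplicated regions, two pseudogene
fragments), rediscovers every locus and prints the resulting gene names.

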