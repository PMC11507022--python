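#!/usr/bin/env python
"""Simulate genome layouts, rediscover the loci, and name the genes.

Two layouts are simulated: a neoteleost-like genome (nine parvalbumin
genes, pvalb2 lost) and a salmonid-like genome (extra WGD: thirteen
intact genes, a pvalb2A/2B tandem on both duplicated regions, and
pseudogene fragments of pvalb1 and pvalb10).  The translated-similarity
scanner rediscovers the loci, which are then named by the tandem-letter
and chromosome-suffix conventions.
"""

import csv
from pathlib import Path

from pvalbid.locus import find_parvalbumin_loci, write_locus_bed
from pvalbid.nomenclature import LocusRecord, assign_locus_names
from pvalbid.panel import bundled_panel
from pvalbid.simulate import (
    chum_salmon_like_plan,
    red_seabream_like_plan,
    simulate_genome,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def run_layout(key, plan, panel):
    label_of = {sc.name: sc.chromosome_label for sc in plan.scaffolds}
    scaffolds, truth = simulate_genome(plan)
    hits = find_parvalbumin_loci(scaffolds, panel)
    write_locus_bed(hits, OUT / f"{key}_loci.bed")
    records = [
        LocusRecord(
            locus_id=f"{h.scaffold}:{h.start}",
            family=h.best_panel_family,
            chromosome_label=label_of[h.scaffold],
            start=h.start, end=h.end, strand=h.strand,
            pseudogene=not h.intact,
        )
        for h in hits
    ]
    names = assign_locus_names(records)
    path = OUT / f"{key}_gene_names.tsv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["locus_id", "gene_symbol", "status"])
        for rec in sorted(records, key=lambda r: r.locus_id):
            writer.writerow(
                [rec.locus_id, names[rec.locus_id].render("gene"),
                 "pseudogene" if rec.pseudogene else "intact"]
            )
    intact = sum(h.intact for h in hits)
    pseudo = len(hits) - intact
    planted = sum(t["kind"] == "intact" for t in truth)
    print(f"{key}: planted {planted} intact -> found {intact} intact "
          f"+ {pseudo} pseudogene fragments")
    print("  " + ", ".join(
        sorted(names[r.locus_id].render("gene") for r in records)))
    return intact, pseudo


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel = bundled_panel()
    run_layout("seabream_like", red_seabream_like_plan(SEED), panel)
    run_layout("chum_like", chum_salmon_like_plan(SEED), panel)
    print(f"wrote BED and name tables under {OUT}")


if __name__ == "__main__":
    main()
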