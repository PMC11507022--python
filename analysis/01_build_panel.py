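#!/usr/bin/env python
"""Export the bundled reference panel and its identity structure.

Writes the panel FASTA/TSV and the all-vs-all percent-identity matrix
(the package's analog of a cross-species parvalbumin identity table)
under results/.
"""

from pathlib import Path

from pvalbid.identity import identity_matrix, write_identity_matrix
from pvalbid.panel import bundled_panel

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel = bundled_panel()
    panel.write(OUT / "panel.fasta", OUT / "panel.tsv")
    matrix = identity_matrix([e.sequence for e in panel.entries])
    write_identity_matrix(matrix, OUT / "panel_identity_matrix.tsv")

    fam = {e.id: e.family for e in panel.entries}
    lin = {e.id: e.lineage for e in panel.entries}
    within = [
        matrix.loc[a, b]
        for a in matrix.index for b in matrix.index
        if a < b and fam[a] == fam[b]
    ]
    cross = [
        matrix.loc[a, b]
        for a in matrix.index for b in matrix.index
        if a < b and lin[a] != lin[b]
    ]
    print(f"panel: {len(panel.entries)} entries, "
          f"{len(panel.families())} families (checksum {panel.checksum()})")
    print(f"mean within-family identity: "
          f"{sum(within) / len(within):.1f}%")
    print(f"mean cross-lineage identity: {sum(cross) / len(cross):.1f}%")
    print(f"wrote {OUT / 'panel_identity_matrix.tsv'}")


if __name__ == "__main__":
    main()
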