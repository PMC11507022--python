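#!/usr/bin/env python
"""Discover diagnostic residue positions from the labelled panel.

Derives family-level and lineage-level rule sets, writes them as TSV,
and highlights the positions that separate the hard Beta-2 families
(pvalb2/pvalb3/pvalb4 at canonical positions 12, 16 and 19).
"""

from pathlib import Path

from pvalbid.motifs import derive_diagnostic_positions
from pvalbid.panel import bundled_panel

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel = bundled_panel()
    for grouping in ("family", "lineage"):
        rules = derive_diagnostic_positions(panel, grouping)
        path = OUT / f"diagnostic_rules_{grouping}.tsv"
        rules.write(path)
        print(f"{grouping}: {len(rules.rules)} rules across "
              f"{len(rules.groups())} groups -> {path}")

    rules = derive_diagnostic_positions(panel, "family")
    print("\nkey positions for the hard Beta-2 calls:")
    for group in ("pvalb2", "pvalb3", "pvalb4"):
        for pos in (12, 16, 19):
            rule = rules.rule_at(group, pos)
            if rule:
                print(f"  {group}@{pos} = {''.join(sorted(rule.allowed))}")


if __name__ == "__main__":
    main()
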