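"""Position profiles, information content, and diagnostic residue rules.

The hard-to-separate parvalbumin families are told apart in practice by
a handful of diagnostic residues (e.g. position 12 Thr and position 19
Gln for pvalb3; position 12 Ala plus a small residue at 19 for pvalb2;
acidic 16 and Lys 19 for pvalb4).  This module discovers such positions
from a labelled panel and scores queries against them.
"""

from __future__ import annotations

import csv
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .panel import (
    CANONICAL_LENGTH,
    CanonicalAlignment,
    ReferencePanel,
    map_to_canonical,
)

#: residues counted as "small" side chains (the pvalb2 position-19 class)
SMALL = frozenset("GASCT")

MAX_BITS = math.log2(20)

#: majority threshold for rule discovery: a group's residue set must
#: cover >= this fraction of its members before it can define a rule
MAJORITY_THRESHOLD = 0.8


@dataclass(frozen=True)
class PositionProfile:
    """Residue frequencies of one canonical column of a sequence group."""

    position: int
    frequencies: dict[str, float]
    n_sequences: int
    gap_fraction: float

    @property
    def information_bits(self) -> float:
        """log2(20) minus the Shannon entropy of the column.

        No small-sample correction is applied; gaps (and X) are excluded
        from the distribution and tracked via ``gap_fraction``.
        """
        entropy = -sum(
            f * math.log2(f) for f in self.frequencies.values() if f > 0
        )
        return MAX_BITS - entropy


@dataclass(frozen=True)
class DiagnosticRule:
    group: str
    position: int
    allowed: frozenset[str]
    weight: float = 1.0

    def matches(self, residue: str | None) -> bool:
        # gaps and undetermined residues never satisfy a rule
        if residue is None or residue == "X":
            return False
        return residue in self.allowed


@dataclass
class DiagnosticRuleSet:
    rules: list[DiagnosticRule]

    def __post_init__(self) -> None:
        for r in self.rules:
            if not 1 <= r.position <= CANONICAL_LENGTH:
                raise ValueError(f"rule position {r.position} out of frame")
            if not r.allowed:
                raise ValueError(
                    f"empty allowed set for {r.group}@{r.position}"
                )

    def groups(self) -> list[str]:
        return sorted({r.group for r in self.rules})

    def for_group(self, group: str) -> list[DiagnosticRule]:
        return [r for r in self.rules if r.group == group]

    def rule_at(self, group: str, position: int) -> DiagnosticRule | None:
        for r in self.rules:
            if r.group == group and r.position == position:
                return r
        return None

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["group", "position", "residues", "weight"])
            for r in sorted(self.rules, key=lambda r: (r.group, r.position)):
                writer.writerow(
                    [r.group, r.position, "".join(sorted(r.allowed)), r.weight]
                )

    @classmethod
    def read(cls, path: str | Path) -> "DiagnosticRuleSet":
        rules = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                rules.append(
                    DiagnosticRule(
                        group=row["group"],
                        position=int(row["position"]),
                        allowed=frozenset(row["residues"]),
                        weight=float(row["weight"]),
                    )
                )
        return cls(rules)


@dataclass(frozen=True)
class MotifScore:
    group: str
    matched_rules: int
    total_rules: int
    weighted_score: float


def column_frequencies(
    group: list[CanonicalAlignment],
) -> list[PositionProfile]:
    """One :class:`PositionProfile` per canonical position.

    Frequencies are computed over the 20 standard residues; gaps and X
    are excluded from the distribution and reported as ``gap_fraction``.
    """
    if not group:
        raise ValueError("column_frequencies needs a non-empty group")
    if len(group) < 2:
        raise ValueError("column_frequencies needs >= 2 aligned sequences")
    profiles = []
    n = len(group)
    for pos in range(1, CANONICAL_LENGTH + 1):
        counts: Counter[str] = Counter()
        gaps = 0
        for aln in group:
            res = aln.residue_at(pos)
            if res is None or res == "X":
                gaps += 1
            else:
                counts[res] += 1
        total = sum(counts.values())
        freqs = (
            {res: c / total for res, c in sorted(counts.items())}
            if total
            else {}
        )
        profiles.append(
            PositionProfile(
                position=pos,
                frequencies=freqs,
                n_sequences=n,
                gap_fraction=gaps / n,
            )
        )
    return profiles


def _majority_set(counts: Counter[str]) -> frozenset[str] | None:
    """Smallest residue set covering >= MAJORITY_THRESHOLD of a column."""
    total = sum(counts.values())
    if total == 0:
        return None
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    acc = 0
    chosen = []
    for res, c in ordered:
        chosen.append(res)
        acc += c
        if acc / total >= MAJORITY_THRESHOLD:
            return frozenset(chosen)
    return frozenset(chosen)


def panel_alignments(
    panel: ReferencePanel, grouping: str = "family"
) -> dict[str, list[CanonicalAlignment]]:
    """Canonical alignments of panel members, grouped by family|lineage."""
    if grouping not in ("family", "lineage"):
        raise ValueError("grouping must be 'family' or 'lineage'")
    groups: dict[str, list[CanonicalAlignment]] = {}
    for e in panel.entries:
        key = e.family if grouping == "family" else e.lineage
        groups.setdefault(key, []).append(map_to_canonical(e.sequence, panel))
    return groups


def derive_diagnostic_positions(
    panel: ReferencePanel, grouping: str = "family"
) -> DiagnosticRuleSet:
    """Discover diagnostic positions from the labelled panel.

    A rule ``group@position = allowed`` is emitted when the group's
    minimal >= 80%-majority residue set at a canonical position is
    disjoint from every residue observed in any other group there.
    Groups with fewer than two members are excluded with a warning.
    """
    groups = panel_alignments(panel, grouping)
    usable = {}
    for name, alns in sorted(groups.items()):
        if len(alns) < 2:
            warnings.warn(
                f"group {name!r} has <2 members; excluded from rule discovery"
            )
            continue
        usable[name] = alns

    # per group and position: residue counts (gaps/X dropped)
    observed: dict[str, list[Counter[str]]] = {
        name: [Counter() for _ in range(CANONICAL_LENGTH)]
        for name in usable
    }
    for name, alns in usable.items():
        for aln in alns:
            for pos in range(1, CANONICAL_LENGTH + 1):
                res = aln.residue_at(pos)
                if res is not None and res != "X":
                    observed[name][pos - 1][res] += 1

    rules = []
    for name in sorted(usable):
        for pos in range(1, CANONICAL_LENGTH + 1):
            majority = _majority_set(observed[name][pos - 1])
            if not majority:
                continue
            others: set[str] = set()
            for other in usable:
                if other != name:
                    others |= set(observed[other][pos - 1])
            if majority & others:
                continue
            rules.append(
                DiagnosticRule(group=name, position=pos, allowed=majority)
            )
    return DiagnosticRuleSet(rules)


def score_against_rules(
    aln: CanonicalAlignment, rules: DiagnosticRuleSet
) -> list[MotifScore]:
    """Score a mapped query against every rule group (deterministic order)."""
    if not rules.rules:
        raise ValueError("empty rule set")
    scores = []
    for group in rules.groups():
        group_rules = rules.for_group(group)
        total_w = sum(r.weight for r in group_rules)
        matched = [r for r in group_rules if r.matches(aln.residue_at(r.position))]
        scores.append(
            MotifScore(
                group=group,
                matched_rules=len(matched),
                total_rules=len(group_rules),
                weighted_score=sum(r.weight for r in matched) / total_w,
            )
        )
    return scores


def write_profiles(
    profiles: list[PositionProfile], path: str | Path
) -> None:
    """Export profiles as a tidy TSV consumable by logo-plotting tools."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["position", "residue", "frequency", "information_bits",
             "gap_fraction", "n_sequences"]
        )
        for p in profiles:
            bits = p.information_bits
            for res, freq in p.frequencies.items():
                writer.writerow(
                    [p.position, res, f"{freq:.4f}", f"{bits:.4f}",
                     f"{p.gap_fraction:.4f}", p.n_sequences]
                )
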