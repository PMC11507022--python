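"""Canonical coordinate frame, reference panel, and query mapping.

Residue numbering throughout the package follows a fixed 109-position
canonical frame anchored on the bundled pvalb4 exemplar (the family
whose structure historically defined parvalbumin numbering).  Positions
quoted in the literature — e.g. the diagnostic residues at 12, 16 and
19 — are addressable through :class:`CanonicalAlignment`.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from . import panel_synthetic
from .align import align_global
from .sequences import (
    ParvalbuminSequence,
    read_protein_fasta,
    write_protein_fasta,
)

CANONICAL_LENGTH = 109

LINEAGES = ("Alpha", "Oncomodulin", "Beta2")

#: lineage membership of the ten ancestral teleost families
FAMILY_LINEAGE = dict(panel_synthetic.LINEAGE_OF_FAMILY)
FAMILIES = tuple(panel_synthetic.FAMILIES)

# Approximate helix layout of the six-helix parvalbumin fold (helices
# A-F; the CD and EF inter-helix loops carry the two functional EF-hand
# Ca2+ sites).
_HELIX_SPANS = {
    "A": (8, 18), "B": (26, 33), "C": (40, 50),
    "D": (60, 70), "E": (79, 88), "F": (99, 108),
}


class PanelError(ValueError):
    """Raised for malformed or inconsistent reference panels."""


class NotParvalbuminError(ValueError):
    """Raised when a query cannot be mapped onto the canonical frame."""


def helix_annotation() -> list[str]:
    """Per-position helix label ('A'..'F' or 'loop'), positions 1..109."""
    labels = ["loop"] * CANONICAL_LENGTH
    for helix, (start, end) in _HELIX_SPANS.items():
        for pos in range(start, end + 1):
            labels[pos - 1] = helix
    return labels


@dataclass(frozen=True)
class CanonicalFrame:
    length: int = CANONICAL_LENGTH
    anchor_id: str = panel_synthetic.ANCHOR_ID
    helices: tuple[str, ...] = tuple(helix_annotation())


@dataclass(frozen=True)
class PanelEntry:
    sequence: ParvalbuminSequence
    lineage: str
    family: str
    chromosome_label: str | None = None

    @property
    def id(self) -> str:
        return self.sequence.id


@dataclass
class ReferencePanel:
    """Curated labelled parvalbumins plus per-family consensus profiles."""

    entries: list[PanelEntry]
    consensus: dict[str, str]  # family -> 109-residue consensus
    frame: CanonicalFrame = field(default_factory=CanonicalFrame)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.id in seen:
                raise PanelError(f"duplicate panel entry id {e.id!r}")
            seen.add(e.id)
            if e.family not in FAMILY_LINEAGE:
                raise PanelError(f"{e.id}: unknown family label {e.family!r}")
            if e.lineage not in LINEAGES:
                raise PanelError(f"{e.id}: unknown lineage label {e.lineage!r}")
            if FAMILY_LINEAGE[e.family] != e.lineage:
                raise PanelError(
                    f"{e.id}: lineage/family contradiction — {e.family} "
                    f"belongs to {FAMILY_LINEAGE[e.family]}, not {e.lineage}"
                )
        for family, cons in self.consensus.items():
            if len(cons) != CANONICAL_LENGTH:
                raise PanelError(
                    f"consensus for {family} is {len(cons)} positions, "
                    f"expected {CANONICAL_LENGTH}"
                )

    # -- access helpers -------------------------------------------------
    def families(self) -> list[str]:
        return sorted({e.family for e in self.entries},
                      key=lambda f: int(f.removeprefix("pvalb")))

    def missing_families(self) -> list[str]:
        present = {e.family for e in self.entries}
        return [f for f in FAMILIES if f not in present]

    def by_family(self, family: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.family == family]

    def entry(self, entry_id: str) -> PanelEntry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)

    def chromosomes_of(self, family: str) -> set[str]:
        return {
            chromosome_stem(e.chromosome_label)
            for e in self.by_family(family)
            if e.chromosome_label
        }

    def checksum(self) -> str:
        h = hashlib.sha256()
        for e in sorted(self.entries, key=lambda e: e.id):
            h.update(
                f"{e.id}\t{e.lineage}\t{e.family}\t"
                f"{e.chromosome_label}\t{e.sequence.residues}\n".encode()
            )
        return h.hexdigest()[:16]

    # -- serialization ---------------------------------------------------
    def write(self, fasta_path: str | Path, metadata_path: str | Path) -> None:
        write_protein_fasta([e.sequence for e in self.entries], fasta_path)
        with open(metadata_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["id", "species", "lineage", "family", "chromosome_label"]
            )
            for e in self.entries:
                writer.writerow(
                    [e.id, e.sequence.species, e.lineage, e.family,
                     e.chromosome_label or ""]
                )


def chromosome_stem(label: str | None) -> str:
    """Alphabetic stem of a chromosome/scaffold label.

    WGD-duplicated regions carry numbered variants of one ancestral
    label (Chr.B1, Chr.B2); both match the panel's Chr.B.
    """
    if not label:
        return ""
    return label.strip().rstrip("0123456789")


@dataclass(frozen=True)
class CanonicalAlignment:
    """A query mapped onto canonical positions 1..109.

    ``position_map[i]`` (0-based list, position i+1) holds the query
    residue or None for a gap; insertions relative to the frame are
    recorded but carry no canonical number.
    """

    query_id: str
    position_map: tuple[str | None, ...]
    best_family: str
    score: float
    insertions: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.position_map) != CANONICAL_LENGTH:
            raise ValueError("position_map must cover 109 positions")

    @property
    def coverage(self) -> float:
        occupied = sum(1 for r in self.position_map if r is not None)
        return occupied / CANONICAL_LENGTH

    def residue_at(self, position: int) -> str | None:
        """Residue at canonical position (1-based), or None for a gap."""
        if not 1 <= position <= CANONICAL_LENGTH:
            raise IndexError(f"canonical position {position} out of range")
        return self.position_map[position - 1]

    def occupied_string(self) -> str:
        return "".join(r for r in self.position_map if r is not None)


def load_reference_panel(
    sequences_path: str | Path, metadata_path: str | Path
) -> ReferencePanel:
    """Load a panel from FASTA plus a metadata TSV.

    The TSV requires columns id, species, lineage, family, and an
    optional chromosome_label.  Every FASTA record must be covered by
    metadata; unknown family labels and lineage/family contradictions
    are hard errors.
    """
    seqs = read_protein_fasta(sequences_path, source="reference")
    with open(metadata_path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    required = {"id", "species", "lineage", "family"}
    if rows and not required <= set(rows[0].keys()):
        raise PanelError(
            f"metadata must provide columns {sorted(required)}"
        )
    meta = {row["id"]: row for row in rows}
    orphans = [s.id for s in seqs if s.id not in meta]
    if orphans:
        raise PanelError(f"FASTA records absent from metadata: {orphans}")
    entries = []
    for s in seqs:
        row = meta[s.id]
        entries.append(
            PanelEntry(
                sequence=ParvalbuminSequence(
                    id=s.id, residues=s.residues,
                    species=row.get("species", ""), source="reference",
                ),
                lineage=row["lineage"],
                family=row["family"],
                chromosome_label=row.get("chromosome_label") or None,
            )
        )
    panel = ReferencePanel(
        entries=entries, consensus=panel_synthetic.all_consensuses()
    )
    return panel


def bundled_panel() -> ReferencePanel:
    """The bundled synthetic reference panel (see ``panel_synthetic``)."""
    entries = [
        PanelEntry(sequence=seq, lineage=lineage, family=family,
                   chromosome_label=chrom)
        for seq, lineage, family, chrom in panel_synthetic.build_panel_entries()
    ]
    return ReferencePanel(
        entries=entries, consensus=panel_synthetic.all_consensuses()
    )


def map_to_canonical(
    query: ParvalbuminSequence, panel: ReferencePanel
) -> CanonicalAlignment:
    """Map a query onto the canonical 109-position frame.

    The query is globally aligned against every per-family consensus
    (BLOSUM62, open 10, extend 1, free end gaps); the best-scoring
    family profile provides the coordinate assignment.  Ties go to the
    lexicographically first family, deterministically.
    """
    best: tuple[float, str] | None = None
    for family in sorted(panel.consensus):
        aln = align_global(panel.consensus[family], query.residues)
        if best is None or aln.score > best[0]:
            best = (aln.score, family)
    assert best is not None
    score, family = best
    alignment = align_global(panel.consensus[family], query.residues)

    position_map: list[str | None] = [None] * CANONICAL_LENGTH
    insertions: list[tuple[int, str]] = []
    prev_cons_end = 0
    prev_query_end = 0
    for (c_start, c_end), (q_start, q_end) in zip(*alignment.aligned):
        if q_start > prev_query_end:
            # query residues with no canonical number (insertion)
            insertions.append(
                (prev_cons_end, query.residues[prev_query_end:q_start])
            )
        for k in range(c_end - c_start):
            position_map[c_start + k] = query.residues[q_start + k]
        prev_cons_end, prev_query_end = c_end, q_end
    if prev_query_end < len(query.residues):
        insertions.append((prev_cons_end, query.residues[prev_query_end:]))

    result = CanonicalAlignment(
        query_id=query.id,
        position_map=tuple(position_map),
        best_family=family,
        score=score,
        insertions=tuple(insertions),
    )
    if result.coverage < 0.5:
        raise NotParvalbuminError(
            f"{query.id}: not alignable as parvalbumin "
            f"(canonical coverage {result.coverage:.2f} < 0.5)"
        )
    return result
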