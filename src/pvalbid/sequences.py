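"""Core sequence container and FASTA/TSV plumbing.

Parvalbumins are small EF-hand Ca2+-buffer proteins, typically 108-109
amino acids long.  Everything downstream (canonical mapping, identity,
motif scoring) works on validated :class:`ParvalbuminSequence` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AA_WITH_X = AA_ALPHABET | {"X"}

#: plausibility bounds for a full-length parvalbumin chain
MIN_LENGTH = 90
MAX_LENGTH = 130


class SequenceValidationError(ValueError):
    """Raised when a sequence fails parvalbumin validation."""


@dataclass(frozen=True)
class ParvalbuminSequence:
    """A validated parvalbumin amino-acid sequence.

    Parameters
    ----------
    id :
        Unique record identifier.
    species :
        Free-text species label ("" if unknown).
    residues :
        Uppercase amino-acid string; the 20 standard letters plus ``X``
        for undetermined residues.  ``X`` never counts as a match and
        never satisfies a diagnostic rule.
    source :
        One of ``reference``, ``query``, ``synthetic``.
    """

    id: str
    residues: str
    species: str = ""
    source: str = "query"

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("sequence id must be non-empty")
        if self.source not in ("reference", "query", "synthetic"):
            raise SequenceValidationError(
                f"{self.id}: unknown source {self.source!r}"
            )
        res = self.residues
        if not res:
            raise SequenceValidationError(f"{self.id}: empty sequence")
        bad = set(res) - AA_WITH_X
        if bad:
            raise SequenceValidationError(
                f"{self.id}: invalid residue letters {sorted(bad)}"
            )
        if not (MIN_LENGTH <= len(res) <= MAX_LENGTH):
            raise SequenceValidationError(
                f"{self.id}: length {len(res)} outside plausible "
                f"parvalbumin range [{MIN_LENGTH}, {MAX_LENGTH}]"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def with_id(self, new_id: str) -> "ParvalbuminSequence":
        return replace(self, id=new_id)


def clean_residues(raw: str) -> str:
    """Uppercase and strip whitespace/stops from a raw residue string."""
    return "".join(raw.split()).upper().rstrip("*")


def read_protein_fasta(
    path: str | Path, source: str = "query", species: str = ""
) -> list[ParvalbuminSequence]:
    """Read a protein FASTA into validated sequences.

    Raises :class:`SequenceValidationError` on malformed records so that
    callers can fail fast rather than classify garbage.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    seqs = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceValidationError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(
            ParvalbuminSequence(
                id=rec.id,
                residues=clean_residues(str(rec.seq)),
                species=species,
                source=source,
            )
        )
    return seqs


def write_protein_fasta(
    seqs: Iterable[ParvalbuminSequence], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.species)
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_nucleotide_fasta(path: str | Path) -> dict[str, str]:
    """Read scaffolds as a plain ``{id: sequence}`` dict (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SequenceValidationError(f"duplicate scaffold id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_nucleotide_fasta(scaffolds: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in scaffolds.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
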