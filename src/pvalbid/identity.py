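"""Pairwise percent identity, reference ranking, and identity matrices.

Percent identity is defined as matches divided by aligned residue
pairs — columns where both sequences carry a residue — after global
alignment under the package-wide convention (BLOSUM62, open 10,
extend 1, free end gaps).  ``X`` never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import align_global, aligned_pairs
from .panel import ReferencePanel, PanelEntry
from .sequences import ParvalbuminSequence


@dataclass(frozen=True)
class IdentityResult:
    id_a: str
    id_b: str
    matches: int
    aligned_pairs: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.aligned_pairs


def percent_identity(
    a: ParvalbuminSequence, b: ParvalbuminSequence
) -> IdentityResult:
    """Percent identity between two validated sequences.

    Symmetric in its arguments; identical inputs give exactly 100.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot compute identity of an empty sequence")
    # canonicalize orientation so the computation is literally symmetric
    first, second = sorted((a, b), key=lambda s: (s.residues, s.id))
    alignment = align_global(first.residues, second.residues)
    pairs = aligned_pairs(alignment)
    matches = sum(
        1
        for i, j in pairs
        if first.residues[i] == second.residues[j] and first.residues[i] != "X"
    )
    if not pairs:
        raise ValueError(f"no aligned residues between {a.id} and {b.id}")
    return IdentityResult(
        id_a=a.id, id_b=b.id, matches=matches, aligned_pairs=len(pairs)
    )


def rank_references(
    query: ParvalbuminSequence,
    panel: ReferencePanel,
    restrict_to: set[str] | None = None,
) -> list[tuple[PanelEntry, float]]:
    """Panel entries ordered by descending identity to the query.

    Ties are broken lexicographically by entry id, so the ranking is
    deterministic.  ``restrict_to`` limits the comparison to a set of
    families.
    """
    entries = [
        e for e in panel.entries
        if restrict_to is None or e.family in restrict_to
    ]
    if not entries:
        raise ValueError(
            f"family restriction {sorted(restrict_to or [])} leaves an "
            "empty panel"
        )
    scored = [
        (e, percent_identity(query, e.sequence).percent_identity)
        for e in entries
    ]
    scored.sort(key=lambda t: (-t[1], t[0].id))
    return scored


def identity_matrix(seqs: list[ParvalbuminSequence]) -> pd.DataFrame:
    """Symmetric percent-identity matrix (diagonal exactly 100).

    Each unordered pair is computed once; the result is a DataFrame
    indexed by sequence id, directly exportable as TSV.
    """
    if len(seqs) < 2:
        raise ValueError("identity_matrix needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in identity_matrix input")
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(seqs[i], seqs[j]).percent_identity
            values[i, j] = values[j, i] = pid
    return pd.DataFrame(values, index=ids, columns=ids)


def write_identity_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.round(1).to_csv(path, sep="\t", index_label="id")
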