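"""Synthetic bundled reference panel.

A curated panel of labelled parvalbumins underpins every downstream step
(canonical mapping, identity ranking, diagnostic-rule discovery).  This
module constructs a fully SYNTHETIC stand-in panel: no residue string in
here is a real database record.  The panel is designed to reproduce the
documented *group structure* of teleost parvalbumins:

* three ancient lineages — Alpha, Oncomodulin, Beta-2 — separated by a
  block of lineage-specific residues (~64% cross-lineage identity);
* ten ancestral gene families, pvalb1..pvalb10, with
  pvalb1-5 and pvalb10 in Beta-2, pvalb8/9 in Oncomodulin, pvalb6/7 in
  Alpha;
* the diagnostic residues used in practice to tell the hard Beta-2
  families apart: position 12 (pvalb2 = A, pvalb3 = T), position 16
  (pvalb4 = D/E) and position 19 (pvalb2 = small, pvalb3 = Q,
  pvalb4 = K);
* near-identical family pairs pvalb6/7 and pvalb8/9 (~97% identity)
  that sequence alone cannot resolve, mirroring the real situation where
  only chromosomal context separates them;
* the four ohnologous chromosomal regions: pvalb8-4-1-5 on one
  (Chr.A), pvalb9-2-3-10 on another (Chr.B), pvalb6 and pvalb7 alone on
  the remaining two (Chr.C, Chr.D).

Three entries per family are generated, differing at a few designated
neutral positions, so that per-family frequency profiles are non-trivial
but every diagnostic column stays clean.
"""

from __future__ import annotations

import random

from .sequences import AA_ALPHABET, ParvalbuminSequence

FAMILIES = [f"pvalb{i}" for i in range(1, 11)]

LINEAGE_OF_FAMILY = {
    "pvalb1": "Beta2",
    "pvalb2": "Beta2",
    "pvalb3": "Beta2",
    "pvalb4": "Beta2",
    "pvalb5": "Beta2",
    "pvalb10": "Beta2",
    "pvalb6": "Alpha",
    "pvalb7": "Alpha",
    "pvalb8": "Oncomodulin",
    "pvalb9": "Oncomodulin",
}

#: ancestral chromosomal region of each family (four ohnologous regions)
CHROMOSOME_OF_FAMILY = {
    "pvalb8": "Chr.A",
    "pvalb4": "Chr.A",
    "pvalb1": "Chr.A",
    "pvalb5": "Chr.A",
    "pvalb9": "Chr.B",
    "pvalb2": "Chr.B",
    "pvalb3": "Chr.B",
    "pvalb10": "Chr.B",
    "pvalb6": "Chr.C",
    "pvalb7": "Chr.D",
}

# 109-position scaffold sequence (positions 1..109).  Parvalbumin-shaped
# (two EF-hand-like acidic loops) but synthetic.
_BASE = (
    "SMTDLLKAAD"  #   1-10
    "ISGALSACNA"  #  11-20
    "DSFKHKEFFT"  #  21-30
    "KVGLSGKSAD"  #  31-40
    "DIKKVFGIID"  #  41-50
    "QDKSGFIEED"  #  51-60
    "ELKLFLQNFS"  #  61-70
    "AGARALTDAE"  #  71-80
    "TKAFLKAGDS"  #  81-90
    "DGDGKIGVDE"  #  91-100
    "FTALVKAAE"   # 101-109
)
assert len(_BASE) == 109

# Lineage-defining substitutions (Beta-2 keeps the base residue).
_ALPHA_SUBS = {
    3: "K", 5: "I", 7: "D", 11: "V", 22: "N", 25: "Q", 27: "A", 33: "A",
    38: "T", 41: "E", 44: "R", 47: "N", 52: "N", 57: "A", 61: "G", 66: "I",
    69: "Y", 74: "K", 76: "I", 82: "R", 85: "I", 87: "S", 91: "E", 96: "L",
    99: "N", 104: "I", 108: "G",
}
_ONCO_SUBS = {
    3: "R", 5: "V", 7: "E", 11: "L", 22: "D", 25: "N", 27: "M", 33: "S",
    38: "N", 41: "Q", 44: "T", 47: "S", 52: "E", 57: "V", 61: "N", 66: "V",
    69: "W", 74: "Q", 76: "V", 82: "H", 85: "V", 87: "G", 91: "N", 96: "V",
    99: "S", 104: "V", 108: "N",
}
_LINEAGE_SUBS = {"Alpha": _ALPHA_SUBS, "Oncomodulin": _ONCO_SUBS, "Beta2": {}}

# Diagnostic triplet (positions 12, 16, 19) per family.
_DIAG_SUBS = {
    "pvalb1": {12: "S", 16: "S", 19: "N"},
    "pvalb2": {12: "A", 16: "S", 19: "G"},
    "pvalb3": {12: "T", 16: "S", 19: "Q"},
    "pvalb4": {12: "V", 16: "D", 19: "K"},
    "pvalb5": {12: "L", 16: "S", 19: "R"},
    "pvalb10": {12: "I", 16: "S", 19: "M"},
    "pvalb6": {12: "E", 16: "N", 19: "F"},
    "pvalb7": {12: "E", 16: "N", 19: "F"},
    "pvalb8": {12: "K", 16: "G", 19: "Y"},
    "pvalb9": {12: "K", 16: "G", 19: "Y"},
}

# Family-private substitutions (positions owned by exactly one family).
_FAMILY_SUBS = {
    "pvalb1": {23: "Y", 35: "T", 49: "L", 63: "R", 78: "E", 95: "L"},
    "pvalb2": {26: "R", 39: "G", 53: "R", 67: "N", 81: "S", 97: "N"},
    "pvalb3": {28: "Y", 40: "E", 54: "T", 70: "A", 83: "S", 101: "Y"},
    "pvalb4": {29: "L", 42: "V", 56: "Y", 72: "N", 84: "Y", 103: "S"},
    "pvalb5": {6: "I", 21: "E", 30: "S", 43: "R", 55: "A", 64: "I",
               79: "G", 90: "T", 98: "I", 106: "R"},
    "pvalb10": {8: "G", 24: "R", 36: "N", 45: "I", 58: "D", 68: "S",
                80: "D", 93: "E", 102: "S", 107: "G"},
    # near-identical pairs: three residues apart
    "pvalb6": {50: "E", 73: "S", 105: "I"},
    "pvalb7": {50: "N", 73: "G", 105: "L"},
    "pvalb8": {34: "I", 62: "I", 94: "A"},
    "pvalb9": {34: "V", 62: "V", 94: "S"},
}

# Positions free for entry-level (within-family) neutral variation.
NEUTRAL_POSITIONS = [2, 9, 10, 15, 20, 31, 37, 46, 59, 75, 88, 92, 100, 109]

# Alternative diagnostic residues seen in some family members (keeps the
# pvalb4@16 rule a {D, E} set and the pvalb2@19 rule inside SMALL).
_ENTRY_DIAG_VARIANTS = {
    ("pvalb4", "c"): {16: "E"},
    ("pvalb2", "c"): {19: "A"},
}

SPECIES_OF_ENTRY = {"a": "synthetic teleost A", "b": "synthetic teleost B",
                    "c": "synthetic teleost C"}

ANCHOR_ID = "pvalb4_syn_a"  #: defines the 109-position numbering frame


def family_consensus(family: str) -> str:
    """The designed 109-residue consensus of one family."""
    if family not in FAMILIES:
        raise KeyError(f"unknown family {family!r}")
    seq = list(_BASE)
    for pos, res in _LINEAGE_SUBS[LINEAGE_OF_FAMILY[family]].items():
        seq[pos - 1] = res
    for pos, res in _FAMILY_SUBS[family].items():
        seq[pos - 1] = res
    for pos, res in _DIAG_SUBS[family].items():
        seq[pos - 1] = res
    return "".join(seq)


def all_consensuses() -> dict[str, str]:
    return {f: family_consensus(f) for f in FAMILIES}


def _neutral_variant(consensus: str, family: str, entry: str) -> str:
    """Consensus with three deterministic neutral substitutions."""
    rng = random.Random(f"panel:{family}:{entry}")
    seq = list(consensus)
    for pos in sorted(rng.sample(NEUTRAL_POSITIONS, 3)):
        base = seq[pos - 1]
        choices = sorted(AA_ALPHABET - {base})
        seq[pos - 1] = choices[rng.randrange(len(choices))]
    for pos, res in _ENTRY_DIAG_VARIANTS.get((family, entry), {}).items():
        seq[pos - 1] = res
    return "".join(seq)


def build_panel_entries() -> list[tuple[ParvalbuminSequence, str, str, str]]:
    """All bundled entries as (sequence, lineage, family, chromosome).

    Three entries per family; one entry (pvalb1_syn_c) is 108 residues
    long, lacking position 109, as many real parvalbumins do.
    """
    entries = []
    for family in FAMILIES:
        cons = family_consensus(family)
        for entry in ("a", "b", "c"):
            if entry == "a":
                residues = cons
            else:
                residues = _neutral_variant(cons, family, entry)
            if family == "pvalb1" and entry == "c":
                residues = residues[:108]
            seq_id = (
                ANCHOR_ID if (family, entry) == ("pvalb4", "a")
                else f"{family}_syn_{entry}"
            )
            entries.append(
                (
                    ParvalbuminSequence(
                        id=seq_id,
                        residues=residues,
                        species=SPECIES_OF_ENTRY[entry],
                        source="reference",
                    ),
                    LINEAGE_OF_FAMILY[family],
                    family,
                    CHROMOSOME_OF_FAMILY[family],
                )
            )
    return entries
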