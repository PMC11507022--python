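"""Gene-name construction and WHO/IUIS allergen-code handling.

Two naming worlds meet here:

* **Gene-based names** (PVALB1..PVALB10): tandem duplicates get letter
  suffixes (PVALB2A/PVALB2B), whole-genome-duplication copies get
  chromosome suffixes (PVALB4_(Chr.A3)), pseudogenes a Ψ flag.  Gene
  symbols render uppercase, protein names lowercase.

* **WHO/IUIS allergen codes** ("Gad m 1.0201"): species abbreviation,
  allergen number, then four digits — two for the isoallergen (>67% but
  <90% identity groups) and two for the variant (>90% identity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .identity import percent_identity
from .sequences import ParvalbuminSequence

PSEUDOGENE_MARK = "Ψ"  # Ψ

VARIANT_THRESHOLD = 90.0     # > 90%: same isoallergen, new variant
ISOALLERGEN_THRESHOLD = 67.0  # > 67%: same allergen group, new isoallergen


class CodeParseError(ValueError):
    """Malformed WHO/IUIS allergen code."""


# --------------------------------------------------------------------------
# allergen codes

_CODE_RE = re.compile(
    r"^(?P<genus>[A-Z][a-z]{2,3}) (?P<species>[a-z]{1,2}) "
    r"(?P<number>\d+)\.(?P<sub>\d+)$"
)


@dataclass(frozen=True, order=True)
class AllergenCode:
    genus: str          # e.g. "Gad" or "Cten"
    species: str        # e.g. "m" or "sa"
    allergen_number: int
    isoallergen: str    # two digits, "01".."99"
    variant: str        # two digits, "01".."99"

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z][a-z]{2,3}", self.genus):
            raise CodeParseError(f"bad genus abbreviation {self.genus!r}")
        if not re.fullmatch(r"[a-z]{1,2}", self.species):
            raise CodeParseError(f"bad species abbreviation {self.species!r}")
        if self.allergen_number < 1:
            raise CodeParseError("allergen number must be positive")
        for name, digits in (("isoallergen", self.isoallergen),
                             ("variant", self.variant)):
            if not re.fullmatch(r"\d{2}", digits) or not 1 <= int(digits) <= 99:
                raise CodeParseError(
                    f"{name} digits must be 01..99, got {digits!r}"
                )

    @property
    def species_abbrev(self) -> str:
        return f"{self.genus} {self.species}"


def parse_allergen_code(text: str) -> AllergenCode:
    """Parse a WHO/IUIS code such as "Gad m 1.0201".

    Whitespace is normalized; the four-digit sub-numbering is strict.
    """
    normalized = " ".join(text.split())
    m = _CODE_RE.match(normalized)
    if not m:
        # locate the offending part for the error message
        parts = normalized.split(" ")
        if len(parts) < 3:
            raise CodeParseError(
                f"{text!r}: expected 'Abc d N.IIVV' (species abbreviation, "
                "allergen number, four-digit sub-number)"
            )
        raise CodeParseError(
            f"{text!r}: malformed near {parts[min(2, len(parts) - 1)]!r}"
        )
    sub = m.group("sub")
    if len(sub) != 4:
        raise CodeParseError(
            f"{text!r}: sub-numbering must be four digits "
            f"(two for isoallergen, two for variant), got {sub!r} at "
            f"position {normalized.index('.') + 1}"
        )
    return AllergenCode(
        genus=m.group("genus"),
        species=m.group("species"),
        allergen_number=int(m.group("number")),
        isoallergen=sub[:2],
        variant=sub[2:],
    )


def format_allergen_code(code: AllergenCode) -> str:
    """Canonical rendering "Abc d N.IIVV" (inverse of the parser)."""
    return (
        f"{code.genus} {code.species} {code.allergen_number}"
        f".{code.isoallergen}{code.variant}"
    )


# --------------------------------------------------------------------------
# catalog relationships

class Relation(str, Enum):
    same_variant = "same_variant"
    new_variant_of_isoallergen = "new_variant_of_isoallergen"
    new_isoallergen = "new_isoallergen"
    below_isoallergen_threshold = "below_isoallergen_threshold"


@dataclass(frozen=True)
class CatalogRelationship:
    relation: Relation
    anchor_code: AllergenCode
    proposed_code: AllergenCode | None
    supporting_identity: float
    note: str = ""


def relation_from_identity(identity: float) -> Relation:
    """Threshold rule mapping a percent identity to a relation.

    Thresholds are read strictly (">90" for variants, ">67" for
    isoallergens): exactly 90 is isoallergen-level, exactly 67 is below
    threshold.
    """
    if identity >= 100.0:
        return Relation.same_variant
    if identity > VARIANT_THRESHOLD:
        return Relation.new_variant_of_isoallergen
    if identity > ISOALLERGEN_THRESHOLD:
        return Relation.new_isoallergen
    return Relation.below_isoallergen_threshold


def relate_to_catalog(
    query: ParvalbuminSequence,
    catalog: list[tuple[AllergenCode, ParvalbuminSequence]],
) -> CatalogRelationship:
    """Place a query relative to a species' allergen catalog.

    The anchor is the highest-identity catalog entry; the proposed code
    increments the variant digits within the anchor's isoallergen for
    variant-level matches, or takes the next free isoallergen digits
    otherwise.  Below the 67% threshold no code is auto-assigned: such
    cases (e.g. an α-parvalbumin against a β2 catalog) are flagged for
    an expert/clinical decision, which may still keep allergen number 1.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    scored = sorted(
        (
            (percent_identity(query, seq).percent_identity, code)
            for code, seq in catalog
        ),
        key=lambda t: (-t[0], format_allergen_code(t[1])),
    )
    identity, anchor = scored[0]
    relation = relation_from_identity(identity)

    codes = [c for c, _ in catalog]
    if relation is Relation.same_variant:
        proposed: AllergenCode | None = anchor
        note = "identical to the anchor entry"
    elif relation is Relation.new_variant_of_isoallergen:
        used = [
            int(c.variant) for c in codes
            if (c.genus, c.species, c.allergen_number, c.isoallergen)
            == (anchor.genus, anchor.species, anchor.allergen_number,
                anchor.isoallergen)
        ]
        proposed = AllergenCode(
            anchor.genus, anchor.species, anchor.allergen_number,
            anchor.isoallergen, f"{max(used) + 1:02d}",
        )
        note = ""
    elif relation is Relation.new_isoallergen:
        used = [
            int(c.isoallergen) for c in codes
            if (c.genus, c.species, c.allergen_number)
            == (anchor.genus, anchor.species, anchor.allergen_number)
        ]
        proposed = AllergenCode(
            anchor.genus, anchor.species, anchor.allergen_number,
            f"{max(used) + 1:02d}", "01",
        )
        note = ""
    else:
        proposed = None
        note = (
            "below the 67% isoallergen threshold; clinical grouping may "
            "still assign allergen number "
            f"{anchor.allergen_number} — flagged for expert decision"
        )
    return CatalogRelationship(
        relation=relation,
        anchor_code=anchor,
        proposed_code=proposed,
        supporting_identity=round(identity, 2),
        note=note,
    )


# --------------------------------------------------------------------------
# gene names

_GENE_RE = re.compile(
    r"^(?P<stem>PVALB|pvalb)(?P<num>10|[1-9])(?P<letter>[A-Z])?"
    rf"(?P<pseudo>{PSEUDOGENE_MARK})?"
    r"(?:_\((?P<chrom>[^)]+)\))?"
    r"(?:\.(?P<variant>\d{2}))?$"
)


@dataclass(frozen=True)
class GeneName:
    family: str                       # pvalb1..pvalb10
    tandem_letter: str | None = None  # 'A', 'B', ...
    chromosome_suffix: str | None = None
    variant_digits: str | None = None
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if not re.fullmatch(r"pvalb(10|[1-9])", self.family):
            raise ValueError(f"bad family {self.family!r}")
        if self.tandem_letter and not re.fullmatch(r"[A-Z]",
                                                   self.tandem_letter):
            raise ValueError(f"bad tandem letter {self.tandem_letter!r}")
        if self.variant_digits and not re.fullmatch(r"\d{2}",
                                                    self.variant_digits):
            raise ValueError(f"bad variant digits {self.variant_digits!r}")

    def render(self, style: str = "gene") -> str:
        """Render as gene symbol (uppercase) or protein name (lowercase)."""
        if style not in ("gene", "protein"):
            raise ValueError("style must be 'gene' or 'protein'")
        stem = self.family.upper() if style == "gene" else self.family
        out = stem
        if self.tandem_letter:
            out += self.tandem_letter
        if self.pseudogene:
            out += PSEUDOGENE_MARK
        if self.chromosome_suffix:
            out += f"_({self.chromosome_suffix})"
        if self.variant_digits:
            out += f".{self.variant_digits}"
        return out


def parse_gene_name(text: str) -> GeneName:
    """Inverse of :meth:`GeneName.render` (both cases accepted)."""
    m = _GENE_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable gene name {text!r}")
    return GeneName(
        family=f"pvalb{m.group('num')}",
        tandem_letter=m.group("letter"),
        chromosome_suffix=m.group("chrom"),
        variant_digits=m.group("variant"),
        pseudogene=bool(m.group("pseudo")),
    )


@dataclass(frozen=True)
class LocusRecord:
    """One classified genomic locus queued for naming."""

    locus_id: str
    family: str
    chromosome_label: str | None
    start: int
    end: int
    strand: str = "+"
    pseudogene: bool = False


def assign_locus_names(
    loci: list[LocusRecord], species_context: str = ""
) -> dict[str, GeneName]:
    """Assign gene names to a set of classified loci.

    Same family, same chromosome, several intact copies → tandem
    letters A, B, ... in ascending coordinate order.  Same family on
    several chromosomes → chromosome suffixes.  Single-copy family →
    bare name.  Pseudogenes are flagged Ψ and excluded from lettering.
    The assignment is a pure function of (family, chromosome,
    coordinate) and therefore invariant under input permutation.
    """
    by_family: dict[str, list[LocusRecord]] = {}
    for rec in loci:
        by_family.setdefault(rec.family, []).append(rec)

    names: dict[str, GeneName] = {}
    for family, recs in by_family.items():
        chroms = {r.chromosome_label for r in recs}
        multi_chrom = len(chroms) > 1
        if multi_chrom and None in chroms:
            missing = [r.locus_id for r in recs if r.chromosome_label is None]
            raise ValueError(
                f"{family}: loci {missing} lack a chromosome/scaffold label "
                "needed for disambiguation"
            )
        for chrom in chroms:
            group = sorted(
                (r for r in recs if r.chromosome_label == chrom),
                key=lambda r: (r.start, r.end, r.locus_id),
            )
            intact = [r for r in group if not r.pseudogene]
            if len(intact) > 1 and chrom is None:
                raise ValueError(
                    f"{family}: multiple unlabeled loci cannot be "
                    "disambiguated"
                )
            suffix = chrom if multi_chrom else None
            for i, rec in enumerate(intact):
                names[rec.locus_id] = GeneName(
                    family=family,
                    tandem_letter=chr(ord("A") + i) if len(intact) > 1
                    else None,
                    chromosome_suffix=suffix,
                )
            for rec in group:
                if rec.pseudogene:
                    names[rec.locus_id] = GeneName(
                        family=family,
                        chromosome_suffix=suffix,
                        pseudogene=True,
                    )
    return names


# --------------------------------------------------------------------------
# bundled WHO/IUIS catalog table

def load_allergen_table(path: str | Path | None = None) -> pd.DataFrame:
    """The bundled allergen-code / gene-based-name table.

    Columns: species, allergen_code, gene_based_name.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "allergen_catalog.tsv"
    return pd.read_csv(path, sep="\t", dtype=str)
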