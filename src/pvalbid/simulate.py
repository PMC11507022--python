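"""Synthetic fixtures: mutated family sequences, genomes, catalogs.

Every generator is a pure function of its seed and parameters and
returns a *truth record* sufficient to score the downstream operation
(planted family, planted coordinates, planted identity structure)
without peeking at generator internals.

The generators emulate the structures seen in real teleost genomes:
family-consistent protein sequences at a controlled identity to their
consensus with diagnostic residues optionally preserved; two-exon gene
loci spread over the four ohnologous chromosomal regions, including
tandem duplicates, WGD copies, and 5'-fragment pseudogenes with an
internal stop; hybrid genes with one breakpoint; and allergen catalogs
whose isoallergen/variant identity structure matches the WHO/IUIS
thresholds.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .align import blosum62
from .nomenclature import AllergenCode
from .panel_synthetic import (
    CHROMOSOME_OF_FAMILY,
    LINEAGE_OF_FAMILY,
    _FAMILY_SUBS,
    family_consensus,
)
from .sequences import AA_ALPHABET, ParvalbuminSequence

CANONICAL_LENGTH = 109
DIAGNOSTIC_POSITIONS = (12, 16, 19)

MIN_TARGET_IDENTITY = 50.0  # parvalbumins share >45% identity; below 50 is
                            # outside family plausibility

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}


def _blosum_weights(residue: str) -> tuple[list[str], list[float]]:
    """Substitution proposal distribution biased by BLOSUM62 scores."""
    matrix = blosum62()
    letters = sorted(AA_ALPHABET - {residue})
    weights = [math.exp(matrix[residue, x] / 2.0) for x in letters]
    return letters, weights


def preserved_positions(family: str) -> frozenset[int]:
    """Positions never mutated when diagnostics are preserved."""
    return frozenset(DIAGNOSTIC_POSITIONS) | frozenset(_FAMILY_SUBS[family])


def _mutate(
    residues: str,
    n_mutations: int,
    rng: random.Random,
    protected: frozenset[int],
    already: set[int],
) -> tuple[str, set[int]]:
    seq = list(residues)
    free = [
        p for p in range(1, len(seq) + 1)
        if p not in protected and p not in already
    ]
    chosen = rng.sample(free, n_mutations)
    for pos in chosen:
        letters, weights = _blosum_weights(seq[pos - 1])
        seq[pos - 1] = rng.choices(letters, weights=weights, k=1)[0]
    return "".join(seq), already | set(chosen)


def simulate_family_sequence(
    family: str,
    target_identity: float = 90.0,
    preserve_diagnostics: bool = True,
    seed: int = 0,
) -> tuple[ParvalbuminSequence, dict]:
    """A family-consistent sequence at a controlled consensus identity.

    The realized identity is within ±2 points of ``target_identity``
    (exactly (L - m)/L where m substitutions are planted); diagnostic
    positions are untouched when ``preserve_diagnostics``.
    """
    if not MIN_TARGET_IDENTITY <= target_identity <= 100.0:
        raise ValueError(
            f"target identity {target_identity} outside "
            f"[{MIN_TARGET_IDENTITY}, 100]"
        )
    cons = family_consensus(family)
    rng = random.Random(f"seq:{family}:{round(target_identity, 3)}:{seed}")
    n_mut = round((1.0 - target_identity / 100.0) * len(cons))
    protected = preserved_positions(family) if preserve_diagnostics \
        else frozenset()
    residues, mutated = _mutate(cons, n_mut, rng, protected, set())
    seq = ParvalbuminSequence(
        id=f"sim_{family}_t{target_identity:g}_s{seed}",
        residues=residues,
        species="synthetic",
        source="synthetic",
    )
    truth = {
        "family": family,
        "lineage": LINEAGE_OF_FAMILY[family],
        "chromosome_label": CHROMOSOME_OF_FAMILY[family],
        "target_identity": target_identity,
        "realized_identity": 100.0 * (len(cons) - n_mut) / len(cons),
        "mutated_positions": sorted(mutated),
    }
    return seq, truth


def mutation_series(
    family: str,
    targets: list[float],
    seed: int = 0,
    preserve_diagnostics: bool = True,
) -> list[tuple[ParvalbuminSequence, dict]]:
    """Nested mutants at decreasing identity (each extends the last).

    Because substitutions accumulate and never revert, evidence against
    the planted family can only degrade along the series — the fixture
    for confidence-monotonicity checks.
    """
    if sorted(targets, reverse=True) != list(targets):
        raise ValueError("targets must be strictly decreasing")
    cons = family_consensus(family)
    rng = random.Random(f"series:{family}:{seed}")
    protected = preserved_positions(family) if preserve_diagnostics \
        else frozenset()
    out = []
    residues, mutated = cons, set()
    for target in targets:
        if not MIN_TARGET_IDENTITY <= target <= 100.0:
            raise ValueError(f"target identity {target} outside range")
        want = round((1.0 - target / 100.0) * len(cons))
        extra = want - len(mutated)
        if extra > 0:
            residues, mutated = _mutate(
                residues, extra, rng, protected, mutated
            )
        seq = ParvalbuminSequence(
            id=f"series_{family}_t{target:g}_s{seed}",
            residues=residues,
            species="synthetic",
            source="synthetic",
        )
        out.append(
            (seq, {"family": family, "target_identity": target,
                   "mutated_positions": sorted(mutated)})
        )
    return out


def make_hybrid(
    family_a: str, family_b: str, breakpoint: int, seed: int = 0
) -> tuple[ParvalbuminSequence, dict]:
    """A single-breakpoint chimera: positions 1..bp from family_a."""
    if not 10 <= breakpoint <= 99:
        raise ValueError("breakpoint must lie in canonical 10..99")
    if family_a == family_b:
        raise ValueError("hybrid components must differ")
    a, b = family_consensus(family_a), family_consensus(family_b)
    residues = a[:breakpoint] + b[breakpoint:]
    seq = ParvalbuminSequence(
        id=f"hybrid_{family_a}_{family_b}_bp{breakpoint}_s{seed}",
        residues=residues,
        species="synthetic",
        source="synthetic",
    )
    return seq, {"family_a": family_a, "family_b": family_b,
                 "breakpoint": breakpoint}


# --------------------------------------------------------------------------
# genome simulation

@dataclass(frozen=True)
class GenePlan:
    family: str
    strand: str = "+"
    pseudogene: bool = False
    label: str = ""          # e.g. "PVALB2A"; informative only


@dataclass(frozen=True)
class ScaffoldPlan:
    name: str
    chromosome_label: str
    genes: tuple[GenePlan, ...]


@dataclass(frozen=True)
class SimulationPlan:
    seed: int
    scaffolds: tuple[ScaffoldPlan, ...]
    intron_range: tuple[int, int] = (200, 2000)
    spacer_range: tuple[int, int] = (1500, 4000)


def back_translate(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


def _random_nt(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _gene_cassette(
    gene: GenePlan, rng: random.Random, plan: SimulationPlan
) -> tuple[str, dict]:
    """Back-translated two-exon cassette (or 5' pseudogene fragment)."""
    protein = family_consensus(gene.family)
    if gene.pseudogene:
        frag_len = rng.randint(45, 55)
        protein = protein[:frag_len]
        codons = [rng.choice(_CODONS[aa]) for aa in protein]
        codons[frag_len // 2] = "TAA"  # internal stop
        cassette = "".join(codons)
        truth_kind = "pseudogene"
        exon_split = None
    else:
        split = rng.randint(40, 70)  # codon-aligned exon boundary
        exon1 = back_translate(protein[:split], rng)
        exon2 = back_translate(protein[split:], rng)
        intron = _random_nt(rng.randint(*plan.intron_range), rng)
        cassette = exon1 + intron + exon2
        truth_kind = "intact"
        exon_split = (len(exon1), len(exon1) + len(intron))
    if gene.strand == "-":
        import Bio.Seq

        cassette = str(Bio.Seq.Seq(cassette).reverse_complement())
    return cassette, {"kind": truth_kind, "exon_split": exon_split,
                      "protein": protein}


def simulate_genome(plan: SimulationPlan) -> tuple[dict[str, str], list[dict]]:
    """Scaffold FASTA dict plus a truth table of planted loci.

    Each intact gene is embedded as two exons around a random intron;
    pseudogenes as 5' fragments with an internal stop codon.  Truth
    rows carry 0-based half-open coordinates.
    """
    rng = random.Random(f"genome:{plan.seed}")
    scaffolds: dict[str, str] = {}
    truth: list[dict] = []
    for sc in plan.scaffolds:
        if sc.name in scaffolds:
            raise ValueError(f"duplicate scaffold name {sc.name!r}")
        parts: list[str] = [_random_nt(rng.randint(*plan.spacer_range), rng)]
        offset = len(parts[0])
        for i, gene in enumerate(sc.genes):
            cassette, info = _gene_cassette(gene, rng, plan)
            start, end = offset, offset + len(cassette)
            truth.append(
                {
                    "scaffold": sc.name,
                    "chromosome_label": sc.chromosome_label,
                    "start": start,
                    "end": end,
                    "strand": gene.strand,
                    "family": gene.family,
                    "kind": info["kind"],
                    "label": gene.label or gene.family,
                    "protein": info["protein"],
                }
            )
            spacer = _random_nt(rng.randint(*plan.spacer_range), rng)
            parts.extend([cassette, spacer])
            offset = end + len(spacer)
        scaffolds[sc.name] = "".join(parts)
    _check_no_overlap(truth)
    return scaffolds, truth


def _check_no_overlap(truth: list[dict]) -> None:
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for row in truth:
        by_scaffold.setdefault(row["scaffold"], []).append(
            (row["start"], row["end"])
        )
    for name, spans in by_scaffold.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping planned loci on {name}")


def red_seabream_like_plan(seed: int = 0) -> SimulationPlan:
    """Nine intact genes over four regions; the pvalb2 slot is lost,
    as in most neoteleosts."""
    return SimulationPlan(
        seed=seed,
        scaffolds=(
            ScaffoldPlan("scafA1", "Chr.A", (
                GenePlan("pvalb8"), GenePlan("pvalb4", strand="-"),
                GenePlan("pvalb1"), GenePlan("pvalb5"),
            )),
            ScaffoldPlan("scafB1", "Chr.B", (
                GenePlan("pvalb9"), GenePlan("pvalb3", strand="-"),
                GenePlan("pvalb10"),
            )),
            ScaffoldPlan("scafC1", "Chr.C", (GenePlan("pvalb6"),)),
            ScaffoldPlan("scafD1", "Chr.D", (GenePlan("pvalb7"),)),
        ),
    )


def chum_salmon_like_plan(seed: int = 0) -> SimulationPlan:
    """Thirteen intact genes plus two pseudogene fragments.

    Mirrors a salmonid situation: an extra WGD duplicated the regions,
    one duplicate of the pvalb8-4-1-5 region was lost, pvalb3 was lost
    with pvalb2 tandem-duplicated (2A/2B) on both remaining copies, and
    the pvalb1 and one pvalb10 slot hold only pseudogene fragments.
    """
    return SimulationPlan(
        seed=seed,
        scaffolds=(
            ScaffoldPlan("scafA1", "Chr.A1", (
                GenePlan("pvalb8"), GenePlan("pvalb4", strand="-"),
                GenePlan("pvalb1", pseudogene=True), GenePlan("pvalb5"),
            )),
            ScaffoldPlan("scafB1", "Chr.B1", (
                GenePlan("pvalb9"), GenePlan("pvalb2", label="PVALB2A"),
                GenePlan("pvalb2", label="PVALB2B"), GenePlan("pvalb10"),
            )),
            ScaffoldPlan("scafB2", "Chr.B2", (
                GenePlan("pvalb9"), GenePlan("pvalb2", label="PVALB2A"),
                GenePlan("pvalb2", label="PVALB2B"),
                GenePlan("pvalb10", pseudogene=True),
            )),
            ScaffoldPlan("scafC1", "Chr.C1", (GenePlan("pvalb6"),)),
            ScaffoldPlan("scafC2", "Chr.C2", (GenePlan("pvalb6"),)),
            ScaffoldPlan("scafD1", "Chr.D1", (GenePlan("pvalb7"),)),
        ),
    )


# --------------------------------------------------------------------------
# allergen catalog simulation

def simulate_allergen_catalog(
    n_isoallergens: int,
    variants_per_isoallergen: int,
    seed: int = 0,
    base_family: str = "pvalb2",
) -> tuple[list[tuple[AllergenCode, ParvalbuminSequence]], dict]:
    """A catalog with planted isoallergen/variant identity structure.

    Within-isoallergen pairwise identities are > 90%, cross-isoallergen
    identities fall in (67, 90).  Codes are well-formed
    "Syn sp 1.IIVV".
    """
    if n_isoallergens < 1 or variants_per_isoallergen < 1:
        raise ValueError("need at least one isoallergen and one variant")
    group_block = 12       # substitutions defining each isoallergen
    variant_step = 2       # extra substitutions per additional variant
    needed = n_isoallergens * group_block \
        + variants_per_isoallergen * variant_step
    if needed > CANONICAL_LENGTH - len(DIAGNOSTIC_POSITIONS):
        raise ValueError(
            f"identity structure infeasible: {n_isoallergens} isoallergens "
            f"x {variants_per_isoallergen} variants need {needed} free "
            f"positions on a {CANONICAL_LENGTH}-residue sequence"
        )
    rng = random.Random(f"catalog:{seed}")
    base = family_consensus(base_family)
    positions = [
        p for p in range(1, CANONICAL_LENGTH + 1)
        if p not in DIAGNOSTIC_POSITIONS
    ]
    rng.shuffle(positions)

    catalog: list[tuple[AllergenCode, ParvalbuminSequence]] = []
    truth_groups: dict[str, list[str]] = {}
    cursor = 0
    variant_pool = positions[n_isoallergens * group_block:]
    for iso in range(1, n_isoallergens + 1):
        group_positions = positions[cursor : cursor + group_block]
        cursor += group_block
        group_seq = list(base)
        for p in group_positions:
            letters, weights = _blosum_weights(group_seq[p - 1])
            group_seq[p - 1] = rng.choices(letters, weights=weights, k=1)[0]
        members = []
        for var in range(1, variants_per_isoallergen + 1):
            seq = list(group_seq)
            # variant > 1 differs from variant 1 by a few substitutions
            for p in variant_pool[: (var - 1) * variant_step]:
                letters, _ = _blosum_weights(base[p - 1])
                seq[p - 1] = letters[(iso + var + p) % len(letters)]
            code = AllergenCode("Syn", "sp", 1, f"{iso:02d}", f"{var:02d}")
            pseq = ParvalbuminSequence(
                id=f"synallergen_{iso:02d}{var:02d}_s{seed}",
                residues="".join(seq),
                species="synthetic",
                source="synthetic",
            )
            catalog.append((code, pseq))
            members.append(pseq.id)
        truth_groups[f"{iso:02d}"] = members
    return catalog, {"isoallergen_members": truth_groups,
                     "base_family": base_family}
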