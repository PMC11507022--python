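"""Lineage and family assignment, and hybrid-gene detection.

The decision procedure mirrors how parvalbumin gene identities are
argued in practice:

1. the lineage (Alpha / Oncomodulin / Beta-2) follows from nearest-
   reference identity, with a motif fallback when the margin is thin;
2. within Beta-2, the pvalb1-4 group is first separated from pvalb5 and
   pvalb10, then the hard pvalb1..4 calls lean on diagnostic residues
   (positions 12/16/19) and identity ranking;
3. pvalb6 vs pvalb7 and pvalb8 vs pvalb9 are deliberately *not*
   resolvable from sequence: only chromosomal context (synteny) decides,
   otherwise an explicit "unresolved" pair call is returned.

Evidence precedence is synteny > diagnostic motif > identity ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .identity import percent_identity, rank_references
from .motifs import DiagnosticRuleSet, derive_diagnostic_positions, score_against_rules
from .panel import (
    CANONICAL_LENGTH,
    CanonicalAlignment,
    FAMILY_LINEAGE,
    ReferencePanel,
    chromosome_stem,
    map_to_canonical,
)
from .sequences import ParvalbuminSequence

#: evidence weights implementing the synteny > motif > identity precedence
EVIDENCE_WEIGHTS = {"synteny": 3.0, "motif": 2.0, "identity": 1.0}

#: identity margin (points) for a lineage call straight from ranking
LINEAGE_MARGIN = 2.0

#: family pairs that sequence alone does not resolve
AMBIGUOUS_PAIRS = (frozenset({"pvalb6", "pvalb7"}),
                   frozenset({"pvalb8", "pvalb9"}))

_RULES_CACHE: dict[tuple[str, str], DiagnosticRuleSet] = {}


def _cached_rules(panel: ReferencePanel, grouping: str) -> DiagnosticRuleSet:
    key = (panel.checksum(), grouping)
    if key not in _RULES_CACHE:
        _RULES_CACHE[key] = derive_diagnostic_positions(panel, grouping)
    return _RULES_CACHE[key]


@dataclass(frozen=True)
class SyntenyContext:
    """Chromosomal context of a locus; any one field may be enough."""

    chromosome_label: str | None = None
    neighbor_genes: tuple[str, ...] = ()
    tandem_neighbors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.chromosome_label or self.neighbor_genes
                or self.tandem_neighbors):
            raise ValueError("SyntenyContext must populate at least one field")


@dataclass(frozen=True)
class Evidence:
    source: str       # synteny | motif | identity
    statement: str
    weight: float
    supports: frozenset[str]  # families consistent with this evidence


@dataclass(frozen=True)
class GeneIdentityCall:
    query_id: str
    lineage: str
    lineage_confidence: float
    family: str              # pvalbN or "pvalbN/M unresolved"
    confidence: float
    evidence: tuple[Evidence, ...]

    @property
    def resolved(self) -> bool:
        return "unresolved" not in self.family

    def families_considered(self) -> frozenset[str]:
        if self.resolved:
            return frozenset({self.family})
        pair = self.family.split()[0]  # e.g. "pvalb8/9"
        stem, second = pair.split("/")
        return frozenset({stem, "pvalb" + second})


@dataclass(frozen=True)
class HybridCallResult:
    query_id: str
    is_hybrid: bool
    component_a: tuple[str, tuple[int, int]] | None = None  # family, span
    component_b: tuple[str, tuple[int, int]] | None = None
    breakpoint: int | None = None
    suggested_family: str | None = None
    note: str = ""


def classify_lineage(
    query: ParvalbuminSequence, panel: ReferencePanel
) -> tuple[str, float]:
    """Assign the query to one of the three ancient lineages.

    The top-ranked reference decides when its identity beats the best
    entry of any other lineage by >= 2 points; otherwise lineage-level
    motif scores decide.  Confidence reflects the margin.
    """
    aln = map_to_canonical(query, panel)  # raises if unalignable
    ranked = rank_references(query, panel)
    top_entry, top_id = ranked[0]
    other = next(
        ((e, pid) for e, pid in ranked if e.lineage != top_entry.lineage),
        None,
    )
    if other is None:
        return top_entry.lineage, 1.0
    margin = top_id - other[1]
    if margin >= LINEAGE_MARGIN:
        return top_entry.lineage, min(1.0, margin / 20.0)
    lineage_rules = _cached_rules(panel, "lineage")
    scores = sorted(
        score_against_rules(aln, lineage_rules),
        key=lambda s: (-s.weighted_score, s.group),
    )
    motif_margin = scores[0].weighted_score - (
        scores[1].weighted_score if len(scores) > 1 else 0.0
    )
    if motif_margin > 0:
        return scores[0].group, min(1.0, motif_margin)
    # full tie: fall back on the ranking with minimal confidence
    return top_entry.lineage, 0.05


def _synteny_candidates(
    synteny: SyntenyContext | None,
    panel: ReferencePanel,
    lineage_families: set[str],
) -> tuple[set[str] | None, Evidence | None]:
    if synteny is None or not synteny.chromosome_label:
        return None, None
    stem = chromosome_stem(synteny.chromosome_label)
    hits = {
        f for f in lineage_families
        if stem in panel.chromosomes_of(f)
    }
    if not hits:
        warnings.warn(
            f"chromosome label {synteny.chromosome_label!r} unknown to the "
            "panel; falling back to motif+identity evidence"
        )
        return None, None
    ev = Evidence(
        source="synteny",
        statement=(
            f"chromosome {synteny.chromosome_label} carries "
            f"{'/'.join(sorted(hits))} in the reference layout"
        ),
        weight=EVIDENCE_WEIGHTS["synteny"],
        supports=frozenset(hits),
    )
    return hits, ev


_SUBGROUPS = ({"pvalb1", "pvalb2", "pvalb3", "pvalb4"}, {"pvalb5"},
              {"pvalb10"})


def _beta2_subgroup(
    query: ParvalbuminSequence,
    panel: ReferencePanel,
    candidates: set[str],
) -> set[str]:
    """First-stage Beta-2 split: pvalb1-4 vs pvalb5 vs pvalb10."""
    present = [sg & candidates for sg in _SUBGROUPS]
    present = [sg for sg in present if sg]
    if len(present) <= 1:
        return candidates
    best, best_id = None, -1.0
    for sg in present:
        top = rank_references(query, panel, restrict_to=sg)[0]
        if top[1] > best_id:
            best, best_id = sg, top[1]
    assert best is not None
    return best


def classify_family(
    query: ParvalbuminSequence,
    panel: ReferencePanel,
    rules: DiagnosticRuleSet | None = None,
    synteny: SyntenyContext | None = None,
) -> GeneIdentityCall:
    """Full gene-identity call for one query sequence.

    Returns a resolved family, or an explicit "pvalbN/M unresolved"
    call for the pairs that need chromosomal context.  Confidence is the
    weighted fraction of concordant evidence.
    """
    aln = map_to_canonical(query, panel)
    lineage, lin_conf = classify_lineage(query, panel)
    if rules is None:
        rules = _cached_rules(panel, "family")

    lineage_families = {
        f for f in panel.families() if FAMILY_LINEAGE[f] == lineage
    }
    evidence: list[Evidence] = []

    syn_hits, syn_ev = _synteny_candidates(synteny, panel, lineage_families)
    candidates = set(syn_hits) if syn_hits else set(lineage_families)
    if syn_ev:
        evidence.append(syn_ev)

    if lineage == "Beta2":
        candidates = _beta2_subgroup(query, panel, candidates)

    # diagnostic-motif evidence over the candidate groups
    cand_scores = [
        s for s in score_against_rules(aln, rules) if s.group in candidates
    ]
    motif_best: set[str] = set()
    if cand_scores:
        top_score = max(s.weighted_score for s in cand_scores)
        motif_best = {
            s.group for s in cand_scores if s.weighted_score == top_score
        }
        evidence.append(
            Evidence(
                source="motif",
                statement=(
                    f"diagnostic residues best match "
                    f"{'/'.join(sorted(motif_best))} "
                    f"(score {top_score:.2f})"
                ),
                weight=EVIDENCE_WEIGHTS["motif"],
                supports=frozenset(motif_best),
            )
        )

    ranked = rank_references(query, panel, restrict_to=candidates)
    identity_best = ranked[0][0].family
    evidence.append(
        Evidence(
            source="identity",
            statement=(
                f"highest identity to {ranked[0][0].id} "
                f"({ranked[0][1]:.1f}%, family {identity_best})"
            ),
            weight=EVIDENCE_WEIGHTS["identity"],
            supports=frozenset({identity_best}),
        )
    )

    # precedence: synteny already restricted candidates; motif next
    pool = motif_best & candidates if motif_best else set(candidates)
    if not pool:
        pool = set(candidates)
    if len(pool) > 1:
        in_pool = [(e, pid) for e, pid in ranked if e.family in pool]
        pool_best = in_pool[0][0].family
        runner = next(
            (pid for e, pid in in_pool if e.family != pool_best), None
        )
        if runner is None or in_pool[0][1] - runner >= 1.0:
            pool = {pool_best}
        # else: keep the tie; may surface as an unresolved pair below

    family: str
    for pair in AMBIGUOUS_PAIRS:
        if pool <= pair and len(candidates & pair) == 2:
            # sequence cannot separate these; only synteny could have
            a, b = sorted(pair, key=lambda f: int(f.removeprefix("pvalb")))
            family = f"{a}/{b.removeprefix('pvalb')} unresolved"
            break
    else:
        if len(pool) == 1:
            family = next(iter(pool))
        else:
            a, b = sorted(pool, key=lambda f: int(f.removeprefix("pvalb")))[:2]
            family = f"{a}/{b.removeprefix('pvalb')} unresolved"

    call_support = (
        frozenset({family}) if "unresolved" not in family
        else frozenset(pool)
    )
    concordant = sum(
        e.weight for e in evidence if e.supports & call_support
    )
    total = sum(e.weight for e in evidence)
    confidence = concordant / total if total else 0.0

    return GeneIdentityCall(
        query_id=query.id,
        lineage=lineage,
        lineage_confidence=round(lin_conf, 4),
        family=family,
        confidence=round(confidence, 4),
        evidence=tuple(evidence),
    )


# ---------------------------------------------------------------------------
# hybrid genes


def detect_hybrid(
    query: ParvalbuminSequence,
    panel: ReferencePanel,
    window: int = 20,
    step: int = 1,
    margin: float = 5.0,
    min_segment_windows: int = 3,
) -> HybridCallResult:
    """Detect intergenic-recombination hybrids by sliding-window identity.

    The query is compared window-by-window against its two closest
    family consensuses; a hybrid is declared when the favored family
    switches exactly once along the sequence, each segment favoring its
    family by >= ``margin`` identity points.  The suggested name follows
    the gene's unique (minority) part.
    """
    if window < 10:
        raise ValueError("window must be >= 10 canonical positions")
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(query.residues) < window:
        raise ValueError(
            f"{query.id}: sequence shorter than the window ({window})"
        )
    aln = map_to_canonical(query, panel)

    # two closest family consensuses by whole-length canonical identity
    def frame_identity(family: str) -> float:
        cons = panel.consensus[family]
        pairs = [
            (r, cons[i]) for i, r in enumerate(aln.position_map)
            if r is not None
        ]
        if not pairs:
            return 0.0
        return 100.0 * sum(a == b for a, b in pairs) / len(pairs)

    by_identity = sorted(
        panel.consensus, key=lambda f: (-frame_identity(f), f)
    )
    fam_a, fam_b = by_identity[0], by_identity[1]
    cons = {fam_a: panel.consensus[fam_a], fam_b: panel.consensus[fam_b]}

    labels: list[tuple[int, int, str]] = []  # (start, end, label) windows
    for start in range(1, CANONICAL_LENGTH - window + 2, step):
        end = start + window - 1
        occupied = [
            i for i in range(start, end + 1)
            if aln.position_map[i - 1] is not None
        ]
        if len(occupied) < window // 2:
            continue
        ids = {}
        for fam, cseq in cons.items():
            matches = sum(
                1 for i in occupied if aln.position_map[i - 1] == cseq[i - 1]
            )
            ids[fam] = 100.0 * matches / len(occupied)
        if ids[fam_a] - ids[fam_b] >= margin:
            labels.append((start, end, fam_a))
        elif ids[fam_b] - ids[fam_a] >= margin:
            labels.append((start, end, fam_b))

    # compress consecutive same-label windows into segments
    segments: list[tuple[str, int, int, int]] = []  # label, first, last, count
    for start, end, lab in labels:
        if segments and segments[-1][0] == lab:
            prev = segments[-1]
            segments[-1] = (lab, prev[1], end, prev[3] + 1)
        else:
            segments.append((lab, start, end, 1))

    strong = [s for s in segments if s[3] >= min_segment_windows]
    if len(strong) <= 1:
        return HybridCallResult(query_id=query.id, is_hybrid=False)
    if len(strong) > 2 or len(segments) > 2:
        return HybridCallResult(
            query_id=query.id, is_hybrid=False, note="complex mosaic"
        )
    (lab1, s1, e1, _), (lab2, s2, e2, _) = strong
    if lab1 == lab2:
        return HybridCallResult(
            query_id=query.id, is_hybrid=False, note="complex mosaic"
        )
    breakpoint = (e1 + s2) // 2
    span_a = (1, breakpoint)
    span_b = (breakpoint + 1, CANONICAL_LENGTH)
    # the unique (minority) part names the gene
    suggested = lab1 if (span_a[1] - span_a[0]) <= (span_b[1] - span_b[0]) \
        else lab2
    return HybridCallResult(
        query_id=query.id,
        is_hybrid=True,
        component_a=(lab1, span_a),
        component_b=(lab2, span_b),
        breakpoint=breakpoint,
        suggested_family=suggested,
    )
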