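"""Translated-similarity locus finder for genomic scaffolds.

A deliberately small seed-extend-chain search: exact protein 5-mers of
the panel's family consensuses seed ungapped diagonal segments in all
six reading frames; segments are score-filtered (BLOSUM62, threshold
60), then chained collinearly per strand and family with a 10 kb gap
limit.  A chained locus is flagged non-intact (pseudogene-like) when
its translation covers less than 70% of the canonical frame or carries
an internal stop.

Coordinates are 0-based half-open internally and in the BED-like
export; human-readable reports elsewhere use 1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

from .align import blosum62
from .panel import CANONICAL_LENGTH, ReferencePanel

SEED_K = 5
SEGMENT_SCORE_MIN = 60.0
CHAIN_GAP_NT = 10_000
XDROP = 10.0
SEED_JOIN_GAP_AA = 10
PROT_OVERLAP_AA = 20
BLOCK_JOIN_GAP_NT = 45
INTACT_COVERAGE = 0.70


@dataclass(frozen=True)
class GenomicLocusHit:
    scaffold: str
    strand: str                       # '+' or '-'
    exon_blocks: tuple[tuple[int, int], ...]  # 0-based half-open, sorted
    best_panel_family: str
    chained_score: float
    intact: bool
    protein_coverage: float

    @property
    def start(self) -> int:
        return self.exon_blocks[0][0]

    @property
    def end(self) -> int:
        return self.exon_blocks[-1][1]


@dataclass(frozen=True)
class _Segment:
    family: str
    frame: int            # 0..5 (3..5 = reverse strand)
    prot_start: int       # 0-based, inclusive
    prot_end: int         # exclusive
    aa_start: int         # frame coordinates
    aa_end: int
    score: float
    translation: str

    @property
    def strand(self) -> str:
        return "+" if self.frame < 3 else "-"


def _six_frames(seq: str) -> list[str]:
    rc = str(Seq(seq).reverse_complement())
    frames = []
    for src in (seq, rc):
        for f in range(3):
            sub = src[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()))
    return frames


def _frame_to_genomic(frame: int, aa_start: int, aa_end: int, length: int
                      ) -> tuple[int, int]:
    f = frame % 3
    nt_start = f + 3 * aa_start
    nt_end = f + 3 * aa_end
    if frame < 3:
        return nt_start, nt_end
    return length - nt_end, length - nt_start


def _kmer_index(panel: ReferencePanel) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for family, cons in sorted(panel.consensus.items()):
        for i in range(len(cons) - SEED_K + 1):
            index.setdefault(cons[i : i + SEED_K], []).append((family, i))
    return index


def _segment_score(prot: str, frame_str: str, prot_start: int,
                   aa_start: int, length: int, matrix) -> float:
    score = 0.0
    for k in range(length):
        a, b = prot[prot_start + k], frame_str[aa_start + k]
        if b == "*":
            return -1.0
        score += matrix[a, b]
    return score


def _extend(prot: str, frame_str: str, prot_start: int, prot_end: int,
            aa_start: int, aa_end: int, matrix) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of a diagonal run in both directions."""
    # left
    best_gain, best_k, gain = 0.0, 0, 0.0
    k = 0
    while prot_start - k - 1 >= 0 and aa_start - k - 1 >= 0:
        b = frame_str[aa_start - k - 1]
        if b == "*":
            break
        gain += matrix[prot[prot_start - k - 1], b]
        k += 1
        if gain > best_gain:
            best_gain, best_k = gain, k
        if best_gain - gain > XDROP:
            break
    prot_start -= best_k
    aa_start -= best_k
    # right
    best_gain, best_k, gain = 0.0, 0, 0.0
    k = 0
    while prot_end + k < len(prot) and aa_end + k < len(frame_str):
        b = frame_str[aa_end + k]
        if b == "*":
            break
        gain += matrix[prot[prot_end + k], b]
        k += 1
        if gain > best_gain:
            best_gain, best_k = gain, k
    prot_end += best_k
    aa_end += best_k
    return prot_start, prot_end, aa_start, aa_end


def _frame_segments(
    frame: int, frame_str: str, panel: ReferencePanel,
    index: dict[str, list[tuple[str, int]]],
) -> list[_Segment]:
    matrix = blosum62()
    # seed positions per (family, diagonal)
    diagonals: dict[tuple[str, int], list[int]] = {}
    for i in range(len(frame_str) - SEED_K + 1):
        for family, ppos in index.get(frame_str[i : i + SEED_K], ()):
            diagonals.setdefault((family, i - ppos), []).append(i)

    segments = []
    for (family, diag), positions in sorted(diagonals.items()):
        prot = panel.consensus[family]
        positions.sort()
        runs: list[tuple[int, int]] = []
        run_start = positions[0]
        prev = positions[0]
        for p in positions[1:]:
            if p - prev > SEED_JOIN_GAP_AA:
                runs.append((run_start, prev + SEED_K))
                run_start = p
            prev = p
        runs.append((run_start, prev + SEED_K))
        for aa_start, aa_end in runs:
            prot_start, prot_end = aa_start - diag, aa_end - diag
            if "*" in frame_str[aa_start:aa_end]:
                # split at stops; keep sub-runs
                sub = frame_str[aa_start:aa_end]
                offset = 0
                for part in sub.split("*"):
                    if len(part) >= SEED_K:
                        segments.extend(
                            _finish_segment(
                                family, frame, prot,
                                prot_start + offset, prot_start + offset + len(part),
                                aa_start + offset, aa_start + offset + len(part),
                                frame_str, matrix,
                            )
                        )
                    offset += len(part) + 1
                continue
            segments.extend(
                _finish_segment(
                    family, frame, prot, prot_start, prot_end,
                    aa_start, aa_end, frame_str, matrix,
                )
            )
    return segments


def _finish_segment(family, frame, prot, prot_start, prot_end,
                    aa_start, aa_end, frame_str, matrix) -> list[_Segment]:
    prot_start, prot_end, aa_start, aa_end = _extend(
        prot, frame_str, prot_start, prot_end, aa_start, aa_end, matrix
    )
    score = _segment_score(
        prot, frame_str, prot_start, aa_start, prot_end - prot_start, matrix
    )
    if score < SEGMENT_SCORE_MIN:
        return []
    return [
        _Segment(
            family=family, frame=frame,
            prot_start=prot_start, prot_end=prot_end,
            aa_start=aa_start, aa_end=aa_end,
            score=score,
            translation=frame_str[aa_start:aa_end],
        )
    ]


def _chain(segments: list[_Segment], scaffold_len: int
           ) -> list[list[_Segment]]:
    """Greedy collinear chaining in transcription order."""
    if not segments:
        return []
    strand = segments[0].strand

    def genomic(seg: _Segment) -> tuple[int, int]:
        return _frame_to_genomic(
            seg.frame, seg.aa_start, seg.aa_end, scaffold_len
        )

    # transcription order: 5'->3' of the gene
    order = sorted(
        segments,
        key=lambda s: genomic(s)[0] if strand == "+" else -genomic(s)[1],
    )
    chains: list[list[_Segment]] = []
    for seg in order:
        best_chain, best_gap = None, None
        for chain in chains:
            last = chain[-1]
            lg, sg = genomic(last), genomic(seg)
            gap = (sg[0] - lg[1]) if strand == "+" else (lg[0] - sg[1])
            # protein coordinates must progress past the previous exon.
            # A modest overlap is tolerated (X-drop extension can overrun
            # an exon boundary into the intron) but large regressions are
            # rejected so chains cannot hop into a neighboring gene of
            # the same family.  Among eligible chains the genomically
            # closest wins, keeping exons with their own gene.
            if -30 <= gap <= CHAIN_GAP_NT and \
                    seg.prot_start >= last.prot_end - PROT_OVERLAP_AA:
                if best_gap is None or abs(gap) < abs(best_gap):
                    best_chain, best_gap = chain, gap
        if best_chain is not None:
            best_chain.append(seg)
        else:
            chains.append([seg])
    return chains


def find_parvalbumin_loci(
    scaffolds: dict[str, str], panel: ReferencePanel
) -> list[GenomicLocusHit]:
    """Locate parvalbumin-like loci on nucleotide scaffolds.

    Returns maximal same-strand collinear chains of translated-
    similarity segments; overlapping chains of different families are
    merged, keeping the best-scoring family label.  An empty result is
    valid.
    """
    index = _kmer_index(panel)
    hits: list[GenomicLocusHit] = []
    for name in sorted(scaffolds):
        seq = scaffolds[name]
        frames = _six_frames(seq)
        segs: list[_Segment] = []
        for frame, frame_str in enumerate(frames):
            segs.extend(_frame_segments(frame, frame_str, panel, index))
        segs = sorted(set(segs), key=lambda s: (s.family, s.frame, s.aa_start))
        candidates: list[GenomicLocusHit] = []
        for strand in "+-":
            for family in sorted({s.family for s in segs}):
                fam_segs = [
                    s for s in segs
                    if s.family == family and s.strand == strand
                ]
                for chain in _chain(fam_segs, len(seq)):
                    candidates.append(
                        _chain_to_hit(name, seq, strand, family, chain)
                    )
        hits.extend(_merge_overlapping(candidates))
    hits.sort(key=lambda h: (h.scaffold, h.start, h.end))
    return hits


def _chain_to_hit(scaffold: str, seq: str, strand: str, family: str,
                  chain: list[_Segment]) -> GenomicLocusHit:
    length = len(seq)
    spans = sorted(
        _frame_to_genomic(s.frame, s.aa_start, s.aa_end, length)
        for s in chain
    )
    # merge near-adjacent spans (e.g. around an in-frame stop codon)
    blocks: list[list[int]] = [list(spans[0])]
    for start, end in spans[1:]:
        if start - blocks[-1][1] <= BLOCK_JOIN_GAP_NT:
            blocks[-1][1] = max(blocks[-1][1], end)
        else:
            blocks.append([start, end])

    has_stop = False
    for start, end in blocks:
        sub = Seq(seq[start:end])
        if strand == "-":
            sub = sub.reverse_complement()
        sub = sub[: len(sub) - len(sub) % 3]
        if "*" in str(sub.translate()):
            has_stop = True
    covered: set[int] = set()
    for s in chain:
        covered.update(range(s.prot_start, s.prot_end))
    coverage = len(covered) / CANONICAL_LENGTH
    return GenomicLocusHit(
        scaffold=scaffold,
        strand=strand,
        exon_blocks=tuple((b[0], b[1]) for b in blocks),
        best_panel_family=family,
        chained_score=sum(s.score for s in chain),
        intact=(coverage >= INTACT_COVERAGE) and not has_stop,
        protein_coverage=round(coverage, 4),
    )


def _merge_overlapping(hits: list[GenomicLocusHit]) -> list[GenomicLocusHit]:
    """Among genomically overlapping same-strand hits keep the best."""
    kept: list[GenomicLocusHit] = []
    for hit in sorted(hits, key=lambda h: -h.chained_score):
        clash = any(
            k.strand == hit.strand
            and not (hit.end <= k.start or k.end <= hit.start)
            for k in kept
        )
        if not clash:
            kept.append(hit)
    return kept


def write_locus_bed(hits: list[GenomicLocusHit], path: str | Path) -> None:
    """BED-like TSV: scaffold, start, end, strand, family, intact."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            writer.writerow(
                [h.scaffold, h.start, h.end, h.strand,
                 h.best_panel_family, "intact" if h.intact else "pseudogene"]
            )
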