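"""Shared pairwise-alignment configuration.

One global-alignment convention is used throughout the package:
BLOSUM62, gap open 10, gap extend 1, end gaps free.  Free end gaps make
the convention stable for the common 108-vs-109-residue case where a
parvalbumin simply lacks position 109.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP_OPEN = 10.0
GAP_EXTEND = 1.0


@lru_cache(maxsize=1)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=1)
def global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = blosum62()
    aligner.mode = "global"
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    # free end gaps (semi-global): length differences are not penalized
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def align_global(a: str, b: str):
    """Best global alignment of two residue strings.

    Returns a Biopython alignment; ties are resolved deterministically by
    taking the first optimal alignment.
    """
    # PairwiseAligner rejects letters missing from the matrix alphabet;
    # BLOSUM62 includes X, so validated sequences always work.
    return global_aligner().align(a, b)[0]


def aligned_pairs(alignment) -> list[tuple[int, int]]:
    """(index_a, index_b) for every aligned residue pair (no gaps)."""
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        pairs.extend(
            (a_start + k, b_start + k) for k in range(a_end - a_start)
        )
    return pairs
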