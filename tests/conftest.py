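from __future__ import annotations

from pathlib import Path

import pytest

from pvalbid.classify import _cached_rules
from pvalbid.panel import ReferencePanel, bundled_panel

#: directory where a user may install the published (non-redistributed)
#: sequences needed for the literature-value checks
PUBLISHED_DIR = Path(__file__).parent / "data" / "published"

#: record ids the literature-value checks require in published.fasta
PUBLISHED_IDS = (
    "seabream_pvalb3",
    "zebrafish_pvalb3",
    "zebrafish_pvalb2",
    "Gad_m_1.0101",
    "Gad_m_1.0102",
)


@pytest.fixture(scope="session")
def panel() -> ReferencePanel:
    return bundled_panel()


@pytest.fixture(scope="session")
def family_rules(panel):
    return _cached_rules(panel, "family")


def load_published_sequences():
    """Published parvalbumin sequences, if the user installed them.

    These records are public database entries that this package does
    not redistribute; drop a ``published.fasta`` with the ids listed in
    ``PUBLISHED_IDS`` into ``tests/data/published/`` to enable the
    literature-value checks.
    """
    from pvalbid.sequences import read_protein_fasta

    path = PUBLISHED_DIR / "published.fasta"
    if not path.exists():
        return None
    seqs = {s.id: s for s in read_protein_fasta(path)}
    if not all(i in seqs for i in PUBLISHED_IDS):
        return None
    return seqs
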