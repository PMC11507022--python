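import pytest

from pvalbid.classify import (
    SyntenyContext,
    classify_family,
    classify_lineage,
    detect_hybrid,
)
from pvalbid.panel_synthetic import (
    CHROMOSOME_OF_FAMILY,
    FAMILIES,
    LINEAGE_OF_FAMILY,
    family_consensus,
)
from pvalbid.sequences import ParvalbuminSequence
from pvalbid.simulate import make_hybrid, mutation_series, simulate_family_sequence


def _seq(sid, residues):
    return ParvalbuminSequence(id=sid, residues=residues, source="synthetic")


class TestLineage:
    def test_exact_oncomodulin_copy_has_full_confidence(self, panel):
        query = panel.entry("pvalb8_syn_a").sequence.with_id("q")
        lineage, conf = classify_lineage(query, panel)
        assert lineage == "Oncomodulin"
        assert conf == 1.0

    @pytest.mark.parametrize("family", FAMILIES)
    def test_consensus_queries_recover_their_lineage(self, panel, family):
        lineage, _ = classify_lineage(_seq("q", family_consensus(family)),
                                      panel)
        assert lineage == LINEAGE_OF_FAMILY[family]

    def test_alpha_like_query_called_alpha(self, panel):
        # an alpha-lineage parvalbumin diverged from both panel families
        seq, _ = simulate_family_sequence("pvalb7", 86.0, True, seed=11)
        lineage, _ = classify_lineage(seq, panel)
        assert lineage == "Alpha"


class TestFamilyCall:
    def test_t12_q19_and_identity_give_pvalb3(self, panel):
        # mechanizes the archetypal seabream-style argument: T12/Q19
        # plus higher identity to pvalb3 references
        seq, _ = simulate_family_sequence("pvalb3", 88.0, True, seed=2)
        call = classify_family(seq, panel)
        assert call.family == "pvalb3"
        sources = [e.source for e in call.evidence]
        assert "motif" in sources and "identity" in sources

    def test_a12_small19_and_identity_give_pvalb2(self, panel):
        seq, _ = simulate_family_sequence("pvalb2", 88.0, True, seed=3)
        call = classify_family(seq, panel)
        assert call.family == "pvalb2"

    def test_oncomodulin_pair_needs_synteny(self, panel):
        seq, truth = simulate_family_sequence("pvalb8", 90.0, True, seed=4)
        without = classify_family(seq, panel)
        assert without.family == "pvalb8/9 unresolved"
        assert without.families_considered() == {"pvalb8", "pvalb9"}
        with_syn = classify_family(
            seq, panel,
            synteny=SyntenyContext(chromosome_label=truth["chromosome_label"]),
        )
        assert with_syn.family == "pvalb8"

    def test_alpha_pair_needs_synteny(self, panel):
        seq, truth = simulate_family_sequence("pvalb7", 90.0, True, seed=4)
        assert classify_family(seq, panel).family == "pvalb6/7 unresolved"
        call = classify_family(
            seq, panel,
            synteny=SyntenyContext(chromosome_label=truth["chromosome_label"]),
        )
        assert call.family == "pvalb7"

    def test_unknown_chromosome_falls_back_with_warning(self, panel):
        seq, _ = simulate_family_sequence("pvalb3", 90.0, True, seed=5)
        with pytest.warns(UserWarning, match="unknown to the panel"):
            call = classify_family(
                seq, panel, synteny=SyntenyContext(chromosome_label="Chr.Z9")
            )
        assert call.family == "pvalb3"

    def test_family_lineage_always_consistent(self, panel):
        for family in FAMILIES:
            seq, truth = simulate_family_sequence(family, 87.0, True, seed=6)
            call = classify_family(
                seq, panel,
                synteny=SyntenyContext(
                    chromosome_label=truth["chromosome_label"]),
            )
            for f in call.families_considered():
                assert LINEAGE_OF_FAMILY[f] == call.lineage

    def test_calls_are_deterministic(self, panel):
        seq, _ = simulate_family_sequence("pvalb4", 89.0, True, seed=7)
        a = classify_family(seq, panel)
        b = classify_family(seq, panel)
        assert a == b

    def test_confidence_never_rises_with_mutation_load(self, panel):
        for family in ("pvalb3", "pvalb8"):
            series = mutation_series(family, [95, 85, 75, 65, 55], seed=3)
            syn = SyntenyContext(
                chromosome_label=CHROMOSOME_OF_FAMILY[family])
            confs = [
                classify_family(s, panel, synteny=syn).confidence
                for s, _ in series
            ]
            assert all(a >= b for a, b in zip(confs, confs[1:]))


class TestHybridDetection:
    def test_planted_breakpoint_recovered(self, panel):
        seq, truth = make_hybrid("pvalb3", "pvalb2", breakpoint=30)
        result = detect_hybrid(seq, panel, window=20)
        assert result.is_hybrid
        assert abs(result.breakpoint - truth["breakpoint"]) <= 10
        families = {result.component_a[0], result.component_b[0]}
        assert families == {"pvalb3", "pvalb2"}

    def test_unique_minority_part_names_the_gene(self, panel):
        # 5' third from pvalb3, rest pvalb2: the gene is named after its
        # unique (minority) pvalb3 part
        seq, _ = make_hybrid("pvalb3", "pvalb2", breakpoint=30)
        result = detect_hybrid(seq, panel)
        assert result.suggested_family == "pvalb3"

    def test_pure_consensus_is_not_hybrid(self, panel):
        result = detect_hybrid(_seq("q", family_consensus("pvalb4")), panel)
        assert not result.is_hybrid

    def test_two_switch_mosaic_flagged_not_hybrid(self, panel):
        a = family_consensus("pvalb3")
        b = family_consensus("pvalb2")
        mosaic = _seq("m", a[:35] + b[35:75] + a[75:])
        result = detect_hybrid(mosaic, panel)
        assert not result.is_hybrid
        assert result.note == "complex mosaic"

    def test_window_contract_enforced(self, panel):
        seq = _seq("q", family_consensus("pvalb1"))
        with pytest.raises(ValueError, match="window"):
            detect_hybrid(seq, panel, window=5)
        with pytest.raises(ValueError, match="step"):
            detect_hybrid(seq, panel, step=0)
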