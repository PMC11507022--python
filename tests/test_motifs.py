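import math

import pytest

from pvalbid.motifs import (
    MAX_BITS,
    SMALL,
    DiagnosticRule,
    DiagnosticRuleSet,
    column_frequencies,
    derive_diagnostic_positions,
    score_against_rules,
    write_profiles,
)
from pvalbid.panel import CanonicalAlignment, bundled_panel, map_to_canonical
from pvalbid.panel_synthetic import family_consensus
from pvalbid.sequences import ParvalbuminSequence


def _aln_from_column(residues_per_seq):
    """Alignments whose position 1 carries the given residues, rest A."""
    alns = []
    for i, res in enumerate(residues_per_seq):
        pm = [res] + ["A"] * 108
        alns.append(
            CanonicalAlignment(
                query_id=f"s{i}", position_map=tuple(pm),
                best_family="pvalb1", score=0.0,
            )
        )
    return alns


class TestInformationContent:
    def test_pure_column_has_maximal_bits(self):
        profiles = column_frequencies(_aln_from_column("KKKK"))
        assert profiles[0].information_bits == pytest.approx(math.log2(20))

    def test_uniform_column_has_zero_bits(self):
        alns = _aln_from_column("ACDEFGHIKLMNPQRSTVWY")
        profiles = column_frequencies(alns)
        assert profiles[0].information_bits == pytest.approx(0.0, abs=1e-12)

    def test_fifty_fifty_column(self):
        profiles = column_frequencies(_aln_from_column("KKDD"))
        assert profiles[0].information_bits == pytest.approx(MAX_BITS - 1.0)

    def test_contamination_monotonically_lowers_information(self):
        bits = []
        for n_contam in range(0, 6):
            col = "D" * (10 - n_contam) + "N" * n_contam
            bits.append(column_frequencies(_aln_from_column(col))[0]
                        .information_bits)
        assert bits == sorted(bits, reverse=True)
        assert len(set(bits)) == len(bits)

    def test_order_permutation_invariant(self):
        a = column_frequencies(_aln_from_column("DDNN"))[0]
        b = column_frequencies(_aln_from_column("NDND"))[0]
        assert a.frequencies == b.frequencies

    def test_gaps_tracked_separately(self):
        alns = _aln_from_column("KK")
        gapped = CanonicalAlignment(
            query_id="g", position_map=tuple([None] + ["A"] * 108),
            best_family="pvalb1", score=0.0,
        )
        profiles = column_frequencies(alns + [gapped])
        assert profiles[0].gap_fraction == pytest.approx(1 / 3)
        assert sum(profiles[0].frequencies.values()) == pytest.approx(1.0)

    def test_single_sequence_group_rejected(self):
        with pytest.raises(ValueError):
            column_frequencies(_aln_from_column("K"))


class TestRuleDiscovery:
    def test_literature_rules_recovered_from_panel(self, family_rules):
        # the published diagnostic residues for the hard Beta-2 calls
        assert family_rules.rule_at("pvalb3", 12).allowed == {"T"}
        assert family_rules.rule_at("pvalb3", 19).allowed == {"Q"}
        assert family_rules.rule_at("pvalb2", 12).allowed == {"A"}
        assert family_rules.rule_at("pvalb4", 16).allowed == {"D", "E"}
        assert family_rules.rule_at("pvalb4", 19).allowed == {"K"}

    def test_pvalb2_position_19_is_small(self, family_rules):
        rule = family_rules.rule_at("pvalb2", 19)
        assert rule is not None
        assert rule.allowed <= SMALL

    def test_single_planted_column_yields_single_rule(self, panel):
        base = family_consensus("pvalb1")
        g1 = [base, base, base]
        g2 = [base[:49] + "W" + base[50:]] * 3  # position 50 planted
        entries = []
        from pvalbid.panel import PanelEntry, ReferencePanel

        for i, res in enumerate(g1):
            entries.append(PanelEntry(
                ParvalbuminSequence(id=f"a{i}", residues=res,
                                    source="reference"),
                "Beta2", "pvalb1"))
        for i, res in enumerate(g2):
            entries.append(PanelEntry(
                ParvalbuminSequence(id=f"b{i}", residues=res,
                                    source="reference"),
                "Beta2", "pvalb2"))
        mini = ReferencePanel(entries=entries, consensus=panel.consensus)
        rules = derive_diagnostic_positions(mini, "family")
        assert {(r.group, r.position) for r in rules.rules} == {
            ("pvalb1", 50), ("pvalb2", 50)
        } or {(r.group, r.position) for r in rules.rules} == {
            ("pvalb2", 50)
        }

    def test_small_group_excluded_with_warning(self, panel):
        from pvalbid.panel import PanelEntry, ReferencePanel

        entries = [e for e in panel.entries if e.family != "pvalb9"]
        entries.append(panel.entry("pvalb9_syn_a"))
        reduced = ReferencePanel(entries=entries, consensus=panel.consensus)
        with pytest.warns(UserWarning, match="pvalb9"):
            rules = derive_diagnostic_positions(reduced, "family")
        assert "pvalb9" not in rules.groups()

    def test_rule_set_round_trips_through_tsv(self, family_rules, tmp_path):
        path = tmp_path / "rules.tsv"
        family_rules.write(path)
        back = DiagnosticRuleSet.read(path)
        assert {
            (r.group, r.position, r.allowed, r.weight)
            for r in back.rules
        } == {
            (r.group, r.position, r.allowed, r.weight)
            for r in family_rules.rules
        }


class TestRuleScoring:
    def _query_aln(self, panel, residues, qid="q"):
        return map_to_canonical(
            ParvalbuminSequence(id=qid, residues=residues,
                                source="synthetic"),
            panel,
        )

    def test_t12_q19_scores_pvalb3_perfectly(self, panel, family_rules):
        aln = self._query_aln(panel, family_consensus("pvalb3"))
        scores = {s.group: s for s in score_against_rules(aln, family_rules)}
        assert scores["pvalb3"].weighted_score == 1.0

    def test_a12_small19_scores_pvalb2_perfectly(self, panel, family_rules):
        cons = family_consensus("pvalb2")
        assert cons[11] == "A" and cons[18] in SMALL
        aln = self._query_aln(panel, cons)
        scores = {s.group: s for s in score_against_rules(aln, family_rules)}
        assert scores["pvalb2"].weighted_score == 1.0

    def test_gap_at_rule_position_counts_as_non_match(self, family_rules):
        pm = [None] * 109
        aln = CanonicalAlignment(query_id="g", position_map=tuple(pm),
                                 best_family="pvalb1", score=0.0)
        for s in score_against_rules(aln, family_rules):
            assert s.weighted_score == 0.0

    def test_x_never_satisfies_a_rule(self):
        rule = DiagnosticRule(group="g", position=12, allowed=frozenset("AX"))
        assert not rule.matches("X")
        assert not rule.matches(None)
        assert rule.matches("A")


def test_profile_export_is_tidy(tmp_path, panel):
    alns = [
        map_to_canonical(e.sequence, panel)
        for e in panel.by_family("pvalb4")
    ]
    path = tmp_path / "profile.tsv"
    write_profiles(column_frequencies(alns), path)
    header = path.read_text().splitlines()[0].split("\t")
    assert header[:3] == ["position", "residue", "frequency"]
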