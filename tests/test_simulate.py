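import itertools

import pytest

from pvalbid.identity import percent_identity
from pvalbid.nomenclature import Relation, relate_to_catalog
from pvalbid.panel_synthetic import family_consensus
from pvalbid.sequences import ParvalbuminSequence
from pvalbid.simulate import (
    GenePlan,
    ScaffoldPlan,
    SimulationPlan,
    make_hybrid,
    mutation_series,
    simulate_allergen_catalog,
    simulate_family_sequence,
    simulate_genome,
)


def _cons_seq(family):
    return ParvalbuminSequence(
        id=family, residues=family_consensus(family), source="synthetic"
    )


class TestFamilySequences:
    def test_full_identity_returns_exact_consensus(self):
        seq, _ = simulate_family_sequence("pvalb4", 100.0, True, seed=9)
        assert seq.residues == family_consensus("pvalb4")

    def test_realized_identity_within_two_points(self):
        for target in (90.0, 80.0, 60.0):
            seq, truth = simulate_family_sequence("pvalb3", target, True, 7)
            realized = percent_identity(seq, _cons_seq("pvalb3"))
            assert abs(realized.percent_identity - target) <= 2.0
            assert truth["realized_identity"] == pytest.approx(
                realized.percent_identity, abs=0.5
            )

    def test_diagnostics_preserved(self):
        seq, _ = simulate_family_sequence("pvalb3", 90.0, True, seed=7)
        assert seq.residues[11] == "T" and seq.residues[18] == "Q"

    def test_deterministic_under_seed(self):
        a, _ = simulate_family_sequence("pvalb5", 85.0, True, seed=3)
        b, _ = simulate_family_sequence("pvalb5", 85.0, True, seed=3)
        c, _ = simulate_family_sequence("pvalb5", 85.0, True, seed=4)
        assert a.residues == b.residues
        assert a.residues != c.residues

    def test_target_below_plausibility_rejected(self):
        with pytest.raises(ValueError, match="target identity"):
            simulate_family_sequence("pvalb1", 40.0, True, seed=0)

    def test_mutation_series_is_nested(self):
        series = mutation_series("pvalb2", [95, 85, 75], seed=1)
        muts = [set(t["mutated_positions"]) for _, t in series]
        assert muts[0] <= muts[1] <= muts[2]


class TestGenomeSimulation:
    def test_empty_plan_gives_empty_outputs(self):
        scaffolds, truth = simulate_genome(SimulationPlan(seed=0, scaffolds=()))
        assert scaffolds == {} and truth == []

    def test_truth_records_planted_loci(self):
        plan = SimulationPlan(
            seed=2,
            scaffolds=(
                ScaffoldPlan("s1", "Chr.B", (
                    GenePlan("pvalb2", label="PVALB2A"),
                    GenePlan("pvalb2", label="PVALB2B"),
                    GenePlan("pvalb1", pseudogene=True),
                )),
            ),
        )
        scaffolds, truth = simulate_genome(plan)
        assert len(truth) == 3
        kinds = [t["kind"] for t in truth]
        assert kinds.count("intact") == 2 and kinds.count("pseudogene") == 1
        for row in truth:
            assert 0 <= row["start"] < row["end"] <= len(scaffolds["s1"])

    def test_minus_strand_gene_reverse_complemented(self):
        plan = SimulationPlan(
            seed=3,
            scaffolds=(
                ScaffoldPlan("s1", "Chr.A", (GenePlan("pvalb4", strand="-"),)),
            ),
        )
        scaffolds, truth = simulate_genome(plan)
        row = truth[0]
        from Bio.Seq import Seq

        cassette = scaffolds["s1"][row["start"]: row["end"]]
        forward = str(Seq(cassette).reverse_complement())
        # exon1 of the forward orientation encodes the protein's start
        assert str(Seq(forward[:30]).translate()) == row["protein"][:10]

    def test_determinism(self):
        plan = SimulationPlan(
            seed=5,
            scaffolds=(ScaffoldPlan("s1", "Chr.C", (GenePlan("pvalb6"),)),),
        )
        assert simulate_genome(plan)[0] == simulate_genome(plan)[0]


class TestAllergenCatalog:
    def test_identity_structure_matches_thresholds(self):
        catalog, _ = simulate_allergen_catalog(2, 2, seed=1)
        assert len(catalog) == 4
        for (c1, s1), (c2, s2) in itertools.combinations(catalog, 2):
            pid = percent_identity(s1, s2).percent_identity
            if c1.isoallergen == c2.isoallergen:
                assert pid > 90
            else:
                assert 67 < pid < 90

    def test_relate_recovers_planted_structure(self):
        catalog, _ = simulate_allergen_catalog(2, 2, seed=4)
        for code, seq in catalog:
            others = [(c, s) for c, s in catalog if s.id != seq.id]
            rel = relate_to_catalog(seq.with_id("q"), others)
            if rel.relation is Relation.new_variant_of_isoallergen:
                assert rel.anchor_code.isoallergen == code.isoallergen
            else:
                assert rel.relation is Relation.new_isoallergen
                assert rel.anchor_code.isoallergen != code.isoallergen

    def test_single_entry_catalog(self):
        catalog, _ = simulate_allergen_catalog(1, 1, seed=1)
        (code, seq), = catalog
        rel = relate_to_catalog(seq.with_id("q"), catalog)
        assert rel.relation is Relation.same_variant

    def test_infeasible_structure_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_allergen_catalog(12, 1, seed=0)


def test_hybrid_generator_contract():
    seq, truth = make_hybrid("pvalb3", "pvalb2", 30)
    a, b = family_consensus("pvalb3"), family_consensus("pvalb2")
    assert seq.residues[:30] == a[:30]
    assert seq.residues[30:] == b[30:]
    with pytest.raises(ValueError):
        make_hybrid("pvalb3", "pvalb3", 30)
    with pytest.raises(ValueError):
        make_hybrid("pvalb3", "pvalb2", 5)
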