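import random

import pytest
from hypothesis import given, settings, strategies as st

from pvalbid.nomenclature import (
    AllergenCode,
    CodeParseError,
    GeneName,
    LocusRecord,
    Relation,
    assign_locus_names,
    format_allergen_code,
    load_allergen_table,
    parse_allergen_code,
    parse_gene_name,
    relate_to_catalog,
    relation_from_identity,
)
from pvalbid.panel_synthetic import family_consensus
from pvalbid.sequences import ParvalbuminSequence


def _seq(sid, residues):
    return ParvalbuminSequence(id=sid, residues=residues, source="synthetic")


class TestCodeParsing:
    @pytest.mark.parametrize(
        "text,genus,species,number,iso,var",
        [
            ("Gad m 1.0201", "Gad", "m", 1, "02", "01"),
            ("Sar sa 1.0101", "Sar", "sa", 1, "01", "01"),
            ("Cten i 1.0101", "Cten", "i", 1, "01", "01"),
            ("Pan h 1.0201", "Pan", "h", 1, "02", "01"),
        ],
    )
    def test_examples(self, text, genus, species, number, iso, var):
        code = parse_allergen_code(text)
        assert (code.genus, code.species, code.allergen_number,
                code.isoallergen, code.variant) == (
            genus, species, number, iso, var
        )

    @pytest.mark.parametrize(
        "bad",
        ["Gad m 1.201", "Gad m 1.02010", "gad m 1.0101", "Gad 1.0101",
         "Gad m x.0101", "Gad mmm 1.0101", "G m 1.0101", ""],
    )
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(CodeParseError):
            parse_allergen_code(bad)

    def test_whitespace_normalized(self):
        assert parse_allergen_code("  Seb   m  1.0201 ") == parse_allergen_code(
            "Seb m 1.0201"
        )

    def test_catalog_table_round_trips(self):
        table = load_allergen_table()
        assert len(table) == 23
        for text in table["allergen_code"]:
            assert format_allergen_code(parse_allergen_code(text)) == text

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        genus=st.from_regex(r"[A-Z][a-z]{2,3}", fullmatch=True),
        species=st.from_regex(r"[a-z]{1,2}", fullmatch=True),
        number=st.integers(1, 40),
        iso=st.integers(1, 99),
        var=st.integers(1, 99),
    )
    def test_random_codes_round_trip(self, genus, species, number, iso, var):
        code = AllergenCode(genus, species, number, f"{iso:02d}", f"{var:02d}")
        assert parse_allergen_code(format_allergen_code(code)) == code


@pytest.fixture(scope="module")
def catalog():
    base = family_consensus("pvalb2")
    return [
        (parse_allergen_code("Gad m 1.0101"), _seq("c0101", base)),
    ]


class TestCatalogRelationships:

    def test_identical_query_is_same_variant(self, catalog):
        rel = relate_to_catalog(_seq("q", catalog[0][1].residues), catalog)
        assert rel.relation is Relation.same_variant

    def test_one_mismatch_is_new_variant(self, catalog):
        res = list(catalog[0][1].residues)
        res[40] = "W" if res[40] != "W" else "F"
        rel = relate_to_catalog(_seq("q", "".join(res)), catalog)
        assert rel.relation is Relation.new_variant_of_isoallergen
        assert format_allergen_code(rel.proposed_code) == "Gad m 1.0102"

    def test_80_percent_is_new_isoallergen(self, catalog):
        res = list(catalog[0][1].residues)
        rng = random.Random(1)
        for pos in rng.sample(range(109), 22):  # ~80% identity
            res[pos] = "W" if res[pos] != "W" else "F"
        rel = relate_to_catalog(_seq("q", "".join(res)), catalog)
        assert rel.relation is Relation.new_isoallergen
        assert rel.proposed_code.isoallergen == "02"

    def test_cross_lineage_query_flagged_not_autocoded(self, catalog):
        alpha = family_consensus("pvalb7")
        rel = relate_to_catalog(_seq("q", alpha), catalog)
        assert rel.relation is Relation.below_isoallergen_threshold
        assert rel.proposed_code is None
        assert "clinical" in rel.note

    def test_thresholds_read_strictly(self):
        assert relation_from_identity(90.0) is Relation.new_isoallergen
        assert relation_from_identity(67.0) is \
            Relation.below_isoallergen_threshold
        assert relation_from_identity(90.01) is \
            Relation.new_variant_of_isoallergen
        assert relation_from_identity(100.0) is Relation.same_variant

    def test_relation_depends_only_on_max_identity(self):
        # brute-force oracle: re-derive the relation from the threshold
        # rule for a sweep of identities
        rng = random.Random(7)
        for _ in range(1000):
            identity = rng.uniform(0, 100)
            rel = relation_from_identity(identity)
            if identity >= 100:
                expected = Relation.same_variant
            elif identity > 90:
                expected = Relation.new_variant_of_isoallergen
            elif identity > 67:
                expected = Relation.new_isoallergen
            else:
                expected = Relation.below_isoallergen_threshold
            assert rel is expected


class TestGeneNames:
    def test_tandem_pair_lettered_by_coordinate(self):
        recs = [
            LocusRecord("x", "pvalb2", "Chr.B", 9000, 10000),
            LocusRecord("y", "pvalb2", "Chr.B", 2000, 3000),
        ]
        names = assign_locus_names(recs)
        assert names["y"].render("gene") == "PVALB2A"
        assert names["x"].render("gene") == "PVALB2B"

    def test_wgd_copies_get_chromosome_suffixes(self):
        recs = [
            LocusRecord("a", "pvalb4", "Chr.A3", 100, 1100),
            LocusRecord("b", "pvalb4", "Chr.B3", 100, 1100),
        ]
        names = assign_locus_names(recs)
        assert names["a"].render("gene") == "PVALB4_(Chr.A3)"
        assert names["b"].render("gene") == "PVALB4_(Chr.B3)"

    def test_pseudogene_flagged_and_not_lettered(self):
        recs = [
            LocusRecord("i", "pvalb1", "Chr.A", 100, 1100),
            LocusRecord("p", "pvalb1", "Chr.A", 5000, 5400, pseudogene=True),
        ]
        names = assign_locus_names(recs)
        assert names["i"].render("gene") == "PVALB1"
        assert names["p"].render("gene") == "PVALB1Ψ"

    def test_single_copy_family_gets_bare_name(self):
        names = assign_locus_names(
            [LocusRecord("s", "pvalb6", "Chr.C", 10, 2000)]
        )
        assert names["s"].render("gene") == "PVALB6"
        assert names["s"].render("protein") == "pvalb6"

    def test_permutation_invariance(self):
        recs = [
            LocusRecord("a", "pvalb2", "Chr.B", 100, 1000),
            LocusRecord("b", "pvalb2", "Chr.B", 5000, 6000),
            LocusRecord("c", "pvalb4", "Chr.A", 100, 1000),
        ]
        forward = assign_locus_names(recs)
        backward = assign_locus_names(list(reversed(recs)))
        assert forward == backward

    def test_missing_label_when_needed_is_an_error(self):
        recs = [
            LocusRecord("a", "pvalb4", None, 100, 1000),
            LocusRecord("b", "pvalb4", "Chr.B3", 100, 1000),
        ]
        with pytest.raises(ValueError, match="label"):
            assign_locus_names(recs)

    @pytest.mark.parametrize(
        "text", ["PVALB2A", "pvalb2.01", "PVALB4_(Chr.B3)", "PVALB1Ψ",
                 "pvalb3_(Chr.B12)", "pvalb10"]
    )
    def test_rendered_names_round_trip(self, text):
        parsed = parse_gene_name(text)
        style = "gene" if text[0] == "P" else "protein"
        assert parsed.render(style) == text

    def test_table_gene_names_all_parse(self):
        table = load_allergen_table()
        for text in table["gene_based_name"]:
            parse_gene_name(text)
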