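"""DSL parsing: entity paths, statement model, scoping, validation."""

import pytest
from hypothesis import given, settings, strategies as st

from phenograph.dsl import (
    EntityPath,
    MeasurementStatement,
    MetadataStatement,
    PhenoscriptSyntaxError,
    QualityStatement,
    SemanticDescription,
    TermResolutionError,
    canonical_leaf_paths,
    canonical_path,
    extract_measurements,
    parse_description,
    parse_entity_path,
    to_source,
    validate,
)
from phenograph.registry import OntologyTerm

ANTENNA_PATH = (
    "aism-antenna_with_9_antennomeres > colao-antennal_club > "
    "(aism-flagellomere_5, aism-flagellomere_6, aism-flagellomere_7)"
)


class TestEntityPaths:
    def test_antennal_club_grouping(self, registry):
        path = parse_entity_path(ANTENNA_PATH, registry)
        assert [s.local_name for s in path.steps] == [
            "antenna_with_9_antennomeres",
            "antennal_club",
        ]
        assert path.is_grouped
        assert [g.local_name for g in path.group] == [
            "flagellomere_5",
            "flagellomere_6",
            "flagellomere_7",
        ]

    def test_canonical_path_joins_labels(self, registry):
        path = parse_entity_path("aism-male_organism > aism-pronotum > aism-dorsal_region", registry)
        assert canonical_path(path) == "male organism / pronotum / dorsal region"

    def test_grouped_path_yields_one_key_per_leaf(self, registry):
        path = parse_entity_path(ANTENNA_PATH, registry)
        keys = canonical_leaf_paths(path)
        assert len(keys) == 3
        assert keys[0] == "antenna with 9 antennomeres / antennal club / flagellomere 5"

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_equal_paths_have_equal_keys(self, registry, data):
        pool = sorted(
            (t for t in registry if not t.is_relation and t.prefix in ("AISM", "COLAO")),
            key=lambda t: t.token,
        )
        indices = data.draw(st.lists(st.integers(0, len(pool) - 1), min_size=1, max_size=6))
        path_a = EntityPath(tuple(pool[i] for i in indices))
        path_b = EntityPath(tuple(pool[i] for i in indices))
        assert canonical_path(path_a) == canonical_path(path_b)
        other = data.draw(st.lists(st.integers(0, len(pool) - 1), min_size=1, max_size=6))
        if other != indices:
            assert canonical_path(EntityPath(tuple(pool[i] for i in other))) != canonical_path(path_a)


class TestParsing:
    def test_empty_source_gives_empty_description(self, registry):
        desc = parse_description("", registry)
        assert desc.statements == [] and desc.metadata == []

    @pytest.mark.parametrize("species", ["sakalava", "viettei"])
    def test_statement_count_matches_printed_clause_count(
        self, species, registry, sakalava, viettei, sakalava_clauses, viettei_clauses
    ):
        desc = {"sakalava": sakalava, "viettei": viettei}[species]
        clauses = {"sakalava": sakalava_clauses, "viettei": viettei_clauses}[species]
        assert len(desc.statements) == len(clauses)

    def test_grouping_expands_to_one_statement_per_leaf(self, registry):
        desc = parse_description(f"{ANTENNA_PATH}: pato-present;", registry)
        assert len(desc.statements) == 3
        leaves = [s.subject.leaf.local_name for s in desc.statements]
        assert leaves == ["flagellomere_5", "flagellomere_6", "flagellomere_7"]

    def test_block_scoping_expands_to_full_paths(self, registry):
        block = (
            "aism-male_organism > aism-pronotum {\n"
            "  aism-dorsal_region: pato-convex;\n"
            "  aism-lateral_margin: pato-curved;\n"
            "}\n"
        )
        flat = (
            "aism-male_organism > aism-pronotum > aism-dorsal_region: pato-convex;\n"
            "aism-male_organism > aism-pronotum > aism-lateral_margin: pato-curved;\n"
        )
        assert parse_description(block, registry).statements == parse_description(flat, registry).statements

    def test_statement_order_is_preserved(self, sakalava, sakalava_clauses):
        from phenograph.nl import render_statement

        assert [render_statement(s) for s in sakalava.statements] == sakalava_clauses

    def test_token_source_round_trip(self, registry, sakalava):
        again = parse_description(to_source(sakalava), registry)
        assert again.statements == sakalava.statements
        assert again.metadata == sakalava.metadata
        assert again.annotations == sakalava.annotations

    def test_syntax_error_carries_line_number(self, registry):
        with pytest.raises(PhenoscriptSyntaxError) as err:
            parse_description("aism-pronotum: pato-convex;\naism-pronotum pato-convex;", registry)
        assert err.value.line == 2

    def test_unknown_comparator_is_a_syntax_error(self, registry):
        with pytest.raises(PhenoscriptSyntaxError, match="comparator"):
            parse_description(
                "aism-pronotum: width smaller_than length of aism-pronotum;", registry
            )

    def test_unresolvable_terms_reported_with_line_numbers(self, registry):
        source = "aism-pronotum: pato-convex;\naism-not_a_part: pato-convex;"
        with pytest.raises(TermResolutionError) as err:
            parse_description(source, registry)
        assert err.value.failures[0][0] == 2
        assert "not_a_part" in err.value.failures[0][1]

    def test_duplicate_metadata_key_is_rejected(self, registry):
        source = "@catalog_number http://a\n@catalog_number http://b\n"
        with pytest.raises(PhenoscriptSyntaxError, match="duplicate"):
            parse_description(source, registry)


class TestMeasurements:
    def test_sakalava_body_length(self, sakalava):
        assert extract_measurements(sakalava) == [
            ("male organism", "length", 23.0, "millimeter")
        ]

    def test_viettei_body_length(self, viettei):
        assert extract_measurements(viettei) == [
            ("male organism", "length", 21.5, "millimeter")
        ]

    def test_description_without_measurements(self, registry):
        desc = parse_description("aism-male_organism: pato-ovate;", registry)
        assert extract_measurements(desc) == []

    def test_non_positive_values_rejected(self, registry):
        with pytest.raises(ValueError):
            MeasurementStatement(
                parse_entity_path("aism-male_organism", registry),
                "length",
                0.0,
                registry.resolve("uo-millimeter"),
            )


class TestValidation:
    @pytest.mark.parametrize("species", ["sakalava", "viettei"])
    def test_packaged_descriptions_are_clean(self, species, registry, sakalava, viettei):
        desc = {"sakalava": sakalava, "viettei": viettei}[species]
        assert validate(desc, registry) == []

    def test_unregistered_term_is_reported(self, registry):
        stranger = OntologyTerm("AISM", "imaginary_part", label="imaginary part")
        desc = SemanticDescription(
            statements=[QualityStatement(EntityPath((stranger,)), registry.resolve("pato-ovate"))]
        )
        issues = validate(desc, registry)
        assert [i.code for i in issues] == ["unresolved-term"]

    def test_duplicated_metadata_key_is_reported(self, registry):
        desc = SemanticDescription(
            metadata=[
                MetadataStatement("catalog_number", "http://a"),
                MetadataStatement("catalog_number", "http://b"),
            ]
        )
        assert [i.code for i in validate(desc, registry)] == ["duplicate-metadata-key"]

    def test_relation_used_as_quality_is_reported(self, registry):
        desc = SemanticDescription(
            statements=[
                QualityStatement(
                    EntityPath((registry.resolve("aism-pronotum"),)),
                    registry.resolve("ro-encircles"),
                )
            ]
        )
        assert "relation-as-quality" in [i.code for i in validate(desc, registry)]
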