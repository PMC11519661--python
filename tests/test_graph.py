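"""RDF compilation, deterministic serialization, round trips, nanopubs."""

from datetime import datetime, timezone

import pytest
from rdflib import Dataset, Graph, Literal, URIRef
from rdflib.namespace import RDF

from phenograph.dsl import SemanticDescription, parse_description
from phenograph.graph import (
    DWC,
    HAS_QUALITY,
    PART_OF,
    GraphParseError,
    MissingFieldError,
    Nanopub,
    PhenotypeGraph,
    UnsupportedDialectError,
    ValidationFailedError,
    build_habitat_nanopub,
    build_taxon_nanopub,
    compile,
    isomorphic,
    parse_graph,
    serialize,
    serialize_nanopub,
)

DIALECTS = ["turtle", "ntriples", "trig"]
TS = datetime(2024, 10, 21, tzinfo=timezone.utc)


@pytest.fixture(scope="module")
def sakalava_graph(sakalava, registry):
    return compile(sakalava, registry)


@pytest.fixture(scope="module")
def viettei_graph(viettei, registry):
    return compile(viettei, registry)


class TestCompile:
    def test_minimal_description(self, registry):
        graph = compile(parse_description("aism-male_organism: pato-ovate;", registry), registry)
        organism = graph.node_table["male organism"]
        assert (organism, RDF.type, URIRef(registry.iri(registry.resolve("aism-male_organism")))) in graph.triples
        quality_links = [o for s, p, o in graph.triples if s == organism and p == HAS_QUALITY]
        assert len(quality_links) == 1
        quality_node = quality_links[0]
        assert (quality_node, RDF.type, URIRef(registry.iri(registry.resolve("pato-ovate")))) in graph.triples
        # organism (type+label) + quality (type+label+link) + description node (type+about)
        assert len(graph) == 7

    def test_part_of_edges_follow_path_nesting(self, sakalava_graph):
        child = sakalava_graph.node_table["male organism / pronotum / dorsal region"]
        parent = sakalava_graph.node_table["male organism / pronotum"]
        root = sakalava_graph.node_table["male organism"]
        assert (child, PART_OF, parent) in sakalava_graph.triples
        assert (parent, PART_OF, root) in sakalava_graph.triples

    def test_metadata_block_triples(self, sakalava_graph):
        triples = sakalava_graph.triples
        catalog = [o for s, p, o in triples if p == DWC.catalogNumber]
        assert [str(o) for o in catalog] == ["http://id.luomus.fi/GZ.15827"]
        parents = [o for s, p, o in triples if p == DWC.parentNameUsageID]
        assert [str(o) for o in parents] == ["https://www.gbif.org/species/9074838"]

    def test_node_table_matches_independent_path_enumeration(self, sakalava, sakalava_graph):
        from phenograph.dsl import canonical_path

        expected = set()
        for stmt in sakalava.statements:
            paths = [stmt.subject]
            if hasattr(stmt, "object"):
                paths.append(stmt.object)
            if hasattr(stmt, "reference"):
                paths.append(stmt.reference)
            for path in paths:
                for prefix in path.prefixes():
                    expected.add(canonical_path(prefix))
        assert set(sakalava_graph.node_table) == expected
        # bijection: distinct paths <-> distinct instance nodes
        assert len(set(sakalava_graph.node_table.values())) == len(expected)

    def test_validation_failure_blocks_compilation(self, registry):
        from phenograph.dsl import MetadataStatement

        bad = SemanticDescription(
            metadata=[MetadataStatement("denotes", "a"), MetadataStatement("denotes", "b")]
        )
        with pytest.raises(ValidationFailedError):
            compile(bad, registry)


class TestSerialization:
    @pytest.mark.parametrize("dialect", DIALECTS)
    def test_serialize_twice_is_byte_identical(self, sakalava_graph, dialect):
        assert serialize(sakalava_graph, dialect) == serialize(sakalava_graph, dialect)

    @pytest.mark.parametrize("dialect", DIALECTS)
    def test_round_trip_is_isomorphic(self, sakalava_graph, viettei_graph, dialect):
        for graph in (sakalava_graph, viettei_graph):
            again = parse_graph(serialize(graph, dialect), dialect)
            assert isomorphic(graph, again)

    def test_empty_graph_serializes_to_prefixes_only(self):
        empty = PhenotypeGraph(graph=Graph(bind_namespaces="none"))
        text = serialize(empty, "turtle")
        parsed = Graph().parse(data=text, format="turtle")
        assert len(parsed) == 0

    def test_unsupported_dialect(self, sakalava_graph):
        with pytest.raises(UnsupportedDialectError):
            serialize(sakalava_graph, "rdfxml")

    def test_parse_error_on_malformed_document(self):
        with pytest.raises(GraphParseError):
            parse_graph("this is not turtle @@@", "turtle")

    def test_single_ntriples_statement(self):
        line = (
            "<http://example.org/s> "
            "<http://www.w3.org/1999/02/22-rdf-syntax-ns#type> "
            "<http://example.org/C> .\n"
        )
        assert len(parse_graph(line, "ntriples")) == 1

    def test_rdflib_reparses_turtle_output(self, sakalava_graph):
        text = serialize(sakalava_graph, "turtle")
        assert len(Graph().parse(data=text, format="turtle")) == len(sakalava_graph)


class TestNanopubs:
    def test_taxon_nanopub_assertion_content(self):
        nanopub = build_taxon_nanopub(
            "Scarabaeus sakalava",
            "Montanaro & Tarasov",
            "species",
            "https://www.gbif.org/species/9074838",
            timestamp=TS,
        )
        objects = {str(o) for o in nanopub.assertion.objects()}
        assert "Scarabaeus sakalava" in objects
        assert "https://www.gbif.org/species/9074838" in objects
        assert len(nanopub.head) == 4
        assert len(nanopub.pubinfo) == 2

    def test_taxon_nanopub_is_deterministic(self):
        args = ("Scarabaeus sakalava", "Montanaro & Tarasov", "species", "", TS)
        a = build_taxon_nanopub(args[0], args[1], args[2], args[3], timestamp=TS)
        b = build_taxon_nanopub(args[0], args[1], args[2], args[3], timestamp=TS)
        assert serialize_nanopub(a) == serialize_nanopub(b)

    @pytest.mark.parametrize("taxon", ["Scarabaeus sakalava", "Scarabaeus viettei"])
    def test_habitat_nanopub_links_taxon_to_dry_deciduous_forest(self, taxon):
        nanopub = build_habitat_nanopub(taxon, "dry deciduous forest", timestamp=TS)
        assert Literal("dry deciduous forest") in set(nanopub.assertion.objects())
        assert Literal(taxon) in set(nanopub.assertion.objects())

    def test_trig_output_has_four_named_graphs(self):
        nanopub = build_habitat_nanopub("Scarabaeus viettei", "dry deciduous forest", timestamp=TS)
        dataset = Dataset()
        dataset.parse(data=serialize_nanopub(nanopub), format="trig")
        named = [g for g in dataset.graphs() if len(g) and str(g.identifier) != "urn:x-rdflib:default"]
        assert len(named) == 4

    def test_missing_fields_are_rejected(self):
        with pytest.raises(MissingFieldError):
            build_taxon_nanopub("", "Montanaro & Tarasov")
        with pytest.raises(MissingFieldError):
            build_taxon_nanopub("Scarabaeus sakalava", "")
        with pytest.raises(MissingFieldError):
            build_habitat_nanopub("Scarabaeus sakalava", "")
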