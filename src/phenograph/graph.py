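"""Compile descriptions into typed RDF instance graphs; nanopublications.

The compiler follows standard entity--quality instance modeling: every
distinct anatomical location (canonical entity path) becomes one instance
node typed by its ontology class and chained to its parent with *part of*
(BFO:0000050); each quality becomes an instance node typed by the quality
class and attached to its bearer with *has quality* (RO:0000086).
Relational statements become direct edges between entity instances,
comparisons and measurements become small reified nodes in the tool's own
vocabulary namespace, and header metadata hangs off a description node
using Darwin Core terms where they exist.

Instance nodes are skolem IRIs derived from canonical paths — no blank
nodes anywhere — so serialization can be made byte-stable: the writers
emit sorted prefix declarations followed by sorted triples.  Parsing of
Turtle / N-Triples / TriG is delegated to rdflib, which also provides the
graph-isomorphism check used in tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dataclass_field
from datetime import datetime, timezone
from typing import Iterable, Optional

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import DCTERMS, PROV, RDF, RDFS, XSD

from .dsl import (
    ComparativeStatement,
    EntityPath,
    MeasurementStatement,
    QualityStatement,
    RelationalStatement,
    SemanticDescription,
    canonical_path,
    validate,
)
from .registry import TermRegistry

__all__ = [
    "PhenotypeGraph",
    "Nanopub",
    "compile",
    "serialize",
    "parse_graph",
    "isomorphic",
    "build_taxon_nanopub",
    "build_habitat_nanopub",
    "serialize_nanopub",
    "ValidationFailedError",
    "UnsupportedDialectError",
    "MissingFieldError",
    "GraphParseError",
    "DEFAULT_BASE",
]

DEFAULT_BASE = "http://example.org/phenograph/"
PHS = Namespace(DEFAULT_BASE + "vocab#")
DWC = Namespace("http://rs.tdwg.org/dwc/terms/")
OBO = Namespace("http://purl.obolibrary.org/obo/")
NP = Namespace("http://www.nanopub.org/nschema#")

PART_OF = OBO["BFO_0000050"]
HAS_QUALITY = OBO["RO_0000086"]
HAS_HABITAT = OBO["RO_0002303"]

_DIALECTS = {"turtle": "turtle", "ntriples": "nt", "trig": "trig"}

_METADATA_PREDICATES = {
    "catalog_number": DWC.catalogNumber,
    "parent_name_usage_id": DWC.parentNameUsageID,
    "taxon_id": DWC.taxonID,
    "has_role_in_modeling": PHS.hasRoleInModeling,
    "denotes": PHS.denotes,
}


class ValidationFailedError(ValueError):
    def __init__(self, issues):
        self.issues = issues
        super().__init__(
            "description failed validation: " + "; ".join(i.message for i in issues)
        )


class UnsupportedDialectError(ValueError):
    def __init__(self, dialect: str):
        super().__init__(
            f"unsupported RDF dialect {dialect!r} (expected one of {sorted(_DIALECTS)})"
        )


class MissingFieldError(ValueError):
    pass


class GraphParseError(ValueError):
    """Malformed RDF input; wraps the parser's own message (with location)."""


def _slug(text: str) -> str:
    text = text.lower().replace(" / ", "--").replace(" ", "_")
    return re.sub(r"[^a-z0-9_\-.]", "", text)


@dataclass
class PhenotypeGraph:
    """A typed RDF instance graph plus the path -> node table it was built from."""

    graph: Graph
    base_iri: str = DEFAULT_BASE
    node_table: dict = dataclass_field(default_factory=dict)

    @property
    def triples(self) -> set:
        return set(self.graph)

    def __len__(self) -> int:
        return len(self.graph)


def _standard_namespaces(registry: Optional[TermRegistry]) -> dict[str, str]:
    namespaces = {
        "rdf": str(RDF),
        "rdfs": str(RDFS),
        "xsd": str(XSD),
        "obo": str(OBO),
        "dwc": str(DWC),
        "phs": str(PHS),
    }
    if registry is not None:
        for prefix, base in registry.prefix_table.items():
            # OBO-style bases all collapse onto the shared obo: prefix
            if not base.startswith(str(OBO)):
                namespaces[prefix.lower()] = base
    return namespaces


def compile(
    desc: SemanticDescription,
    registry: TermRegistry,
    base_iri: str = DEFAULT_BASE,
) -> PhenotypeGraph:
    """Compile a validated description into a :class:`PhenotypeGraph`."""
    issues = validate(desc, registry)
    if issues:
        raise ValidationFailedError(issues)
    graph = Graph(bind_namespaces="none")
    for prefix, iri in _standard_namespaces(registry).items():
        graph.bind(prefix, iri)
    node_table: dict[str, URIRef] = {}
    quality_counts: dict[tuple[str, str], int] = {}

    def class_iri(term) -> URIRef:
        return URIRef(registry.iri(term))

    def ensure_node(path: EntityPath) -> URIRef:
        key = canonical_path(path)
        if key in node_table:
            return node_table[key]
        node = URIRef(base_iri + "ind/" + _slug(key))
        node_table[key] = node
        graph.add((node, RDF.type, class_iri(path.leaf)))
        graph.add((node, RDFS.label, Literal(path.leaf.label)))
        if len(path.steps) > 1:
            parent = ensure_node(EntityPath(path.steps[:-1]))
            graph.add((node, PART_OF, parent))
        return node

    def add_quality(bearer: URIRef, bearer_key: str, quality) -> None:
        count = quality_counts.get((bearer_key, quality.local_name), 0)
        quality_counts[(bearer_key, quality.local_name)] = count + 1
        suffix = f"-{count + 1}" if count else ""
        qnode = URIRef(
            base_iri + "q/" + _slug(bearer_key) + "--" + quality.local_name + suffix
        )
        graph.add((qnode, RDF.type, class_iri(quality)))
        graph.add((qnode, RDFS.label, Literal(quality.label)))
        graph.add((bearer, HAS_QUALITY, qnode))

    desc_node = URIRef(base_iri + "description/" + (_slug(desc.taxon_label) or "anonymous"))
    graph.add((desc_node, RDF.type, PHS.SemanticDescription))
    if desc.taxon_label:
        graph.add((desc_node, RDFS.label, Literal(desc.taxon_label)))
    for meta in desc.metadata:
        value = meta.value
        obj = (
            URIRef(value)
            if value.startswith(("http://", "https://", "urn:"))
            else Literal(value)
        )
        graph.add((desc_node, _METADATA_PREDICATES[meta.key], obj))

    root: Optional[URIRef] = None
    for stmt in desc.statements:
        subject_node = ensure_node(stmt.subject)
        if root is None:
            root = node_table[canonical_path(EntityPath(stmt.subject.steps[:1]))]
        if isinstance(stmt, QualityStatement):
            add_quality(subject_node, canonical_path(stmt.subject), stmt.quality)
        elif isinstance(stmt, RelationalStatement):
            object_node = ensure_node(stmt.object)
            graph.add((subject_node, URIRef(registry.iri(stmt.relation)), object_node))
            if stmt.attached_quality is not None:
                add_quality(object_node, canonical_path(stmt.object), stmt.attached_quality)
        elif isinstance(stmt, ComparativeStatement):
            reference_node = ensure_node(stmt.reference)
            cnode = URIRef(
                base_iri
                + "comp/"
                + _slug(canonical_path(stmt.subject))
                + "--"
                + stmt.attribute
                + "--"
                + stmt.comparator
                + "--"
                + stmt.reference_attribute
                + "--"
                + _slug(canonical_path(stmt.reference))
            )
            graph.add((cnode, RDF.type, PHS.Comparison))
            graph.add((cnode, PHS.comparedEntity, subject_node))
            graph.add((cnode, PHS.attribute, Literal(stmt.attribute)))
            graph.add((cnode, PHS.comparator, PHS[stmt.comparator]))
            graph.add((cnode, PHS.referenceAttribute, Literal(stmt.reference_attribute)))
            graph.add((cnode, PHS.referenceEntity, reference_node))
        elif isinstance(stmt, MeasurementStatement):
            mnode = URIRef(
                base_iri
                + "meas/"
                + _slug(canonical_path(stmt.subject))
                + "--"
                + stmt.attribute
            )
            graph.add((mnode, RDF.type, PHS.Measurement))
            graph.add((mnode, PHS.measuredEntity, subject_node))
            graph.add((mnode, PHS.attribute, Literal(stmt.attribute)))
            graph.add((mnode, PHS.value, Literal(repr(stmt.value), datatype=XSD.decimal)))
            graph.add((mnode, PHS.unit, URIRef(registry.iri(stmt.unit))))
    if root is not None:
        graph.add((desc_node, PHS.about, root))
    return PhenotypeGraph(graph=graph, base_iri=base_iri, node_table=node_table)


# ---------------------------------------------------------------------------
# deterministic serialization

_PN_LOCAL = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")


def _term_text(term, namespaces: list[tuple[str, str]]) -> str:
    if isinstance(term, URIRef):
        iri = str(term)
        for prefix, base in namespaces:
            if iri.startswith(base):
                local = iri[len(base):]
                if _PN_LOCAL.match(local) and not local.endswith("."):
                    return f"{prefix}:{local}"
        return f"<{iri}>"
    return term.n3()


def _sorted_triples(graph: Iterable) -> list:
    return sorted(graph, key=lambda t: (str(t[0]), str(t[1]), str(t[2]), repr(t[2])))


def _emit_block(graph: Graph, namespaces: list[tuple[str, str]], indent: str = "") -> list[str]:
    lines = []
    for s, p, o in _sorted_triples(graph):
        pred = "a" if p == RDF.type else _term_text(p, namespaces)
        lines.append(f"{indent}{_term_text(s, namespaces)} {pred} {_term_text(o, namespaces)} .")
    return lines


def _namespace_list(graph: Graph) -> list[tuple[str, str]]:
    pairs = {}
    for prefix, iri in graph.namespaces():
        if prefix and not prefix.startswith("default"):
            pairs[prefix] = str(iri)
    # longest base first so the most specific prefix wins
    return sorted(pairs.items(), key=lambda kv: (-len(kv[1]), kv[0]))


def serialize(pgraph: PhenotypeGraph, dialect: str = "turtle") -> str:
    """Byte-stable serialization (sorted prefixes, sorted triples, no bnodes)."""
    if dialect not in _DIALECTS:
        raise UnsupportedDialectError(dialect)
    graph = pgraph.graph
    if dialect == "ntriples":
        lines = [
            f"{s.n3()} {p.n3()} {o.n3()} ."
            for s, p, o in _sorted_triples(graph)
        ]
        return "\n".join(lines) + ("\n" if lines else "")
    namespaces = _namespace_list(graph)
    header = [f"@prefix {p}: <{iri}> ." for p, iri in sorted(namespaces)]
    if dialect == "turtle":
        return "\n".join(header + [""] + _emit_block(graph, namespaces)) + "\n"
    # trig: the whole instance graph in one named graph block
    graph_name = f"<{pgraph.base_iri}graph>"
    body = [graph_name + " {"] + _emit_block(graph, namespaces, indent="    ") + ["}"]
    return "\n".join(header + [""] + body) + "\n"


def parse_graph(text: str, dialect: str = "turtle") -> PhenotypeGraph:
    """Parse RDF text in one of the supported dialects.

    The node table is reconstructed from instance IRIs (``ind/`` skolem
    nodes keyed by their slug); canonical-path labels are not recoverable
    from RDF alone.
    """
    if dialect not in _DIALECTS:
        raise UnsupportedDialectError(dialect)
    graph = Graph(bind_namespaces="none")
    try:
        if dialect == "trig":
            from rdflib import Dataset

            dataset = Dataset()
            dataset.parse(data=text, format="trig")
            for ctx in dataset.graphs():
                for triple in ctx:
                    graph.add(triple)
            for prefix, iri in dataset.namespaces():
                graph.bind(prefix, iri)
        else:
            graph.parse(data=text, format=_DIALECTS[dialect])
    except Exception as exc:
        raise GraphParseError(f"cannot parse {dialect} input: {exc}") from exc
    node_table = {}
    for subject in set(graph.subjects()):
        text_iri = str(subject)
        if "/ind/" in text_iri:
            node_table[text_iri.rsplit("/ind/", 1)[1]] = subject
    base = DEFAULT_BASE
    for subject in graph.subjects(RDF.type, PHS.SemanticDescription):
        base = str(subject).rsplit("description/", 1)[0]
    return PhenotypeGraph(graph=graph, base_iri=base, node_table=node_table)


def isomorphic(a: PhenotypeGraph, b: PhenotypeGraph) -> bool:
    from rdflib.compare import to_isomorphic

    return to_isomorphic(a.graph) == to_isomorphic(b.graph)


# ---------------------------------------------------------------------------
# nanopublications


@dataclass
class Nanopub:
    """head / assertion / provenance / pubinfo named-graph quartet."""

    uri: str
    head: Graph
    assertion: Graph
    provenance: Graph
    pubinfo: Graph

    def graphs(self) -> list[tuple[str, Graph]]:
        return [
            (f"{self.uri}#head", self.head),
            (f"{self.uri}#assertion", self.assertion),
            (f"{self.uri}#provenance", self.provenance),
            (f"{self.uri}#pubinfo", self.pubinfo),
        ]


def _nanopub_shell(uri: str, creator: str, timestamp: datetime) -> Nanopub:
    head, assertion, provenance, pubinfo = (
        Graph(bind_namespaces="none") for _ in range(4)
    )
    np_uri = URIRef(uri)
    head.add((np_uri, RDF.type, NP.Nanopublication))
    head.add((np_uri, NP.hasAssertion, URIRef(uri + "#assertion")))
    head.add((np_uri, NP.hasProvenance, URIRef(uri + "#provenance")))
    head.add((np_uri, NP.hasPublicationInfo, URIRef(uri + "#pubinfo")))
    provenance.add((URIRef(uri + "#assertion"), PROV.wasAttributedTo, URIRef(creator)))
    pubinfo.add((np_uri, DCTERMS.creator, URIRef(creator)))
    pubinfo.add(
        (
            np_uri,
            DCTERMS.created,
            Literal(timestamp.isoformat(), datatype=XSD.dateTime),
        )
    )
    return Nanopub(uri, head, assertion, provenance, pubinfo)


def build_taxon_nanopub(
    name: str,
    authorship: str,
    rank: str = "species",
    parent_usage: str = "",
    creator: str = DEFAULT_BASE + "agent/anonymous",
    timestamp: Optional[datetime] = None,
    base_iri: str = DEFAULT_BASE,
) -> Nanopub:
    """Nanopublication asserting a new scientific name."""
    if not name:
        raise MissingFieldError("taxon name is required")
    if not authorship:
        raise MissingFieldError("authorship is required")
    timestamp = timestamp or datetime(2024, 10, 21, tzinfo=timezone.utc)
    uri = base_iri + "nanopub/taxon-" + _slug(name)
    nanopub = _nanopub_shell(uri, creator, timestamp)
    taxon = URIRef(uri + "#taxon")
    nanopub.assertion.add((taxon, RDF.type, DWC.Taxon))
    nanopub.assertion.add((taxon, DWC.scientificName, Literal(name)))
    nanopub.assertion.add((taxon, DWC.scientificNameAuthorship, Literal(authorship)))
    nanopub.assertion.add((taxon, DWC.taxonRank, Literal(rank)))
    if parent_usage:
        nanopub.assertion.add((taxon, DWC.parentNameUsageID, URIRef(parent_usage)))
    return nanopub


def build_habitat_nanopub(
    taxon: str,
    habitat_label: str,
    evidence_note: str = "",
    creator: str = DEFAULT_BASE + "agent/anonymous",
    timestamp: Optional[datetime] = None,
    base_iri: str = DEFAULT_BASE,
) -> Nanopub:
    """Nanopublication linking a taxon to a habitat type."""
    if not taxon:
        raise MissingFieldError("taxon is required")
    if not habitat_label:
        raise MissingFieldError("habitat label is required")
    timestamp = timestamp or datetime(2024, 10, 21, tzinfo=timezone.utc)
    uri = base_iri + "nanopub/habitat-" + _slug(taxon) + "--" + _slug(habitat_label)
    nanopub = _nanopub_shell(uri, creator, timestamp)
    if taxon.startswith(("http://", "https://", "urn:")):
        taxon_node = URIRef(taxon)
    else:
        taxon_node = URIRef(uri + "#taxon")
        nanopub.assertion.add((taxon_node, RDF.type, DWC.Taxon))
        nanopub.assertion.add((taxon_node, DWC.scientificName, Literal(taxon)))
    habitat_node = URIRef(uri + "#habitat")
    nanopub.assertion.add((habitat_node, RDFS.label, Literal(habitat_label)))
    nanopub.assertion.add((taxon_node, HAS_HABITAT, habitat_node))
    if evidence_note:
        nanopub.provenance.add(
            (URIRef(uri + "#assertion"), RDFS.comment, Literal(evidence_note))
        )
    return nanopub


def serialize_nanopub(nanopub: Nanopub) -> str:
    """Deterministic TriG for the four named graphs."""
    merged = Graph(bind_namespaces="none")
    namespaces = {
        "np": str(NP),
        "dwc": str(DWC),
        "obo": str(OBO),
        "rdfs": str(RDFS),
        "rdf": str(RDF),
        "xsd": str(XSD),
        "dcterms": str(DCTERMS),
        "prov": str(PROV),
    }
    for prefix, iri in namespaces.items():
        merged.bind(prefix, iri)
    ns_list = _namespace_list(merged)
    lines = [f"@prefix {p}: <{iri}> ." for p, iri in sorted(ns_list)]
    lines.append("")
    for graph_uri, graph in nanopub.graphs():
        lines.append(f"<{graph_uri}> {{")
        lines.extend(_emit_block(graph, ns_list, indent="    "))
        lines.append("}")
    return "\n".join(lines) + "\n"
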