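"""Assembly and SPARQL querying of the biomedical knowledge graph.

Entities extracted from paper text become IRIs under the single ``BKG:``
namespace, minted from normalized surface text (lowercased, spaces to
underscores, residual characters percent-encoded).  Every typed entity
carries one class-membership triple per label, a human-readable
``rdfs:label``, and a ``BKG:from_paper`` annotation naming the document
it came from — the hook provenance tracing uses to find the
``Data_Source`` entity behind a fact.
"""

from __future__ import annotations

from urllib.parse import quote

from rdflib import Graph, Literal, RDF, RDFS, URIRef

from .ner import Document, EntityMention
from .relext import NO_RELATION, RelationAssertion
from .schema import BKG, SchemaGraph

FROM_PAPER = BKG["from_paper"]

GRAPH_FORMATS = {"turtle": "turtle", "ntriples": "nt"}


def mint_entity_iri(surface: str) -> URIRef:
    """Mint an entity IRI from normalized surface text."""
    normalized = "_".join(surface.strip().lower().split())
    return BKG[quote(normalized, safe="_-")]


class KnowledgeGraph:
    """A thin rdflib wrapper holding BKG facts with provenance annotations."""

    def __init__(self, graph: Graph | None = None):
        self.graph = graph if graph is not None else Graph()
        self.graph.bind("BKG", BKG)

    def __len__(self) -> int:
        return len(self.graph)

    def __contains__(self, triple) -> bool:
        return triple in self.graph

    def add(self, triple) -> None:
        self.graph.add(triple)

    def triple_set(self) -> set:
        return set(self.graph)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self.triple_set() == other.triple_set()

    def label_of(self, term) -> str:
        """Human-readable label: ``rdfs:label`` if present, else local name."""
        for label in self.graph.objects(term, RDFS.label):
            return str(label)
        text = str(term)
        if text.startswith(str(BKG)):
            text = text[len(str(BKG)):]
        return text.replace("_", " ")

    def entities_of_class(self, class_name: str) -> list[URIRef]:
        return sorted(self.graph.subjects(RDF.type, BKG[class_name]))

    def paper_ids(self, entity: URIRef) -> set[str]:
        return {str(v) for v in self.graph.objects(entity, FROM_PAPER)}


def assemble(
    mentions: list[EntityMention],
    assertions: list[RelationAssertion],
    schema: SchemaGraph,
    doc: Document,
) -> KnowledgeGraph:
    """Build a knowledge graph from one document's mentions and assertions.

    Mentions with equal normalized surfaces collapse onto a single entity
    node; each distinct (entity, label) gets one class triple.  Relation
    assertions become IRI-to-IRI triples; no-relationship assertions are
    dropped.  Assembly is idempotent: equal inputs give equal graphs.
    """
    kg = KnowledgeGraph()
    for mention in mentions:
        if mention.label not in schema.classes:
            raise ValueError(f"mention label {mention.label!r} not present in schema")
        entity = mint_entity_iri(mention.span.surface)
        kg.add((entity, RDF.type, BKG[mention.label]))
        kg.add((entity, RDFS.label, Literal(mention.span.surface)))
        kg.add((entity, FROM_PAPER, Literal(doc.id)))
    for assertion in assertions:
        if assertion.relation == NO_RELATION:
            continue
        if assertion.relation not in schema.relations:
            raise ValueError(
                f"assertion relation {assertion.relation!r} not present in schema"
            )
        head = mint_entity_iri(assertion.head.span.surface)
        tail = mint_entity_iri(assertion.tail.span.surface)
        kg.add((head, BKG[assertion.relation], tail))
    return kg


def query(kg: KnowledgeGraph, sparql: str) -> list[tuple]:
    """Run a SPARQL 1.1 SELECT/ASK query with the ``BKG:`` prefix bound.

    SELECT rows are tuples of bound terms.  Without an explicit
    ``ORDER BY``, rows are sorted lexicographically for determinism.
    """
    try:
        result = kg.graph.query(
            sparql, initNs={"BKG": BKG, "rdf": RDF, "rdfs": RDFS}
        )
    except Exception as exc:
        raise ValueError(f"SPARQL query failed: {exc}") from exc
    if result.type == "ASK":
        return [(bool(result.askAnswer),)]
    rows = [tuple(row) for row in result]
    if "order by" not in sparql.lower():
        rows.sort(key=lambda r: tuple("" if t is None else str(t) for t in r))
    return rows


def serialize_graph(kg: KnowledgeGraph, format: str = "turtle") -> str:
    """Serialize to Turtle or N-Triples text."""
    if format not in GRAPH_FORMATS:
        raise ValueError(
            f"unsupported format {format!r}; expected one of {sorted(GRAPH_FORMATS)}"
        )
    return kg.graph.serialize(format=GRAPH_FORMATS[format])


def parse_graph(text: str, format: str = "turtle") -> KnowledgeGraph:
    """Parse text produced by :func:`serialize_graph`; round-trips triple sets."""
    if format not in GRAPH_FORMATS:
        raise ValueError(f"unsupported format {format!r}")
    g = Graph()
    try:
        g.parse(data=text, format=GRAPH_FORMATS[format])
    except Exception as exc:
        raise ValueError(f"cannot parse graph document: {exc}") from exc
    return KnowledgeGraph(g)
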