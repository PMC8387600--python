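"""HIPAA-ontology population and the four-signal compliance report.

An organization's privacy policy is reduced to deontic statements, each
statement becomes a rule individual in the HIPAA ontology graph typed by
the COVID guidance subclass a keyword map assigns it (media access,
contacting recovered patients, PHI to law enforcement, telehealth;
unmatched statements attach to the generic CovidRule class).  SPARQL
over the populated graph yields per-subclass coverage; together with the
semantic key-term frequency, the angular document similarity against the
regulation corpus, and the vagueness report, this forms the compliance
report.  Lower similarity and present coverage indicate closer
compliance — the four signals are reported side by side, never collapsed
into one scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping
from urllib.parse import quote

from rdflib import Literal, RDF, RDFS, OWL

from .bkg import KnowledgeGraph
from .ner import Document
from .policy_nlp import (
    DeonticStatement,
    HashingDocEmbedder,
    KeyTermProfile,
    SimilarityScore,
    VagueTaxonomy,
    VaguenessReport,
    doc_similarity,
    semantic_term_frequency,
    vagueness_report,
)
from .relext import EmbeddingProvider
from .schema import HIPAA, HipaaOntologySchema

#: Keyword map from statement text to CovidRule subclass (first hit wins,
#: in this declaration order).  Configurable per deployment.
DEFAULT_RULE_KEYWORDS: dict[str, tuple[str, ...]] = {
    "Media_Access": ("media",),
    "Contacting_Covid19_Patients": ("plasma", "contacting", "contact"),
    "PHI_To_Law_Enforcement": ("law enforcement", "law", "first responder", "responder"),
    "Telehealth": ("telehealth", "remote"),
}

MODALITY = HIPAA["modality"]
RULE_TEXT = HIPAA["ruleText"]


@dataclass
class OrganizationPolicy:
    """A policy document with the deontic statements extracted from it."""

    org_id: str
    document: Document
    statements: list[DeonticStatement] = field(default_factory=list)


@dataclass(frozen=True)
class CoverageEntry:
    status: str  # "covered" | "N/A"
    statements: tuple[str, ...] = ()


@dataclass
class RuleCoverage:
    """Per-CovidRule-subclass coverage; every subclass appears exactly once."""

    entries: dict[str, CoverageEntry]

    def missing(self) -> list[str]:
        return [k for k, e in self.entries.items() if e.status == "N/A"]

    def to_dict(self) -> dict:
        return {
            k: {"status": e.status, "statements": list(e.statements)}
            for k, e in self.entries.items()
        }


@dataclass
class ComplianceReport:
    """The four compliance signals for one organization."""

    org_id: str
    coverage: RuleCoverage
    keyterm_frequency: int
    similarity: SimilarityScore
    vagueness: VaguenessReport

    def to_dict(self) -> dict:
        return {
            "org_id": self.org_id,
            "coverage": self.coverage.to_dict(),
            "keyterm_frequency": self.keyterm_frequency,
            "similarity_radians": self.similarity.radians,
            "vagueness": self.vagueness.to_dict(),
            "report_version": 1,
        }


def _org_iri(org_id: str):
    return HIPAA["org_" + quote("_".join(org_id.strip().lower().split()), safe="_-")]


def hipaa_base_graph(schema: HipaaOntologySchema) -> KnowledgeGraph:
    """Graph holding the ontology's class hierarchy and object properties."""
    kg = KnowledgeGraph()
    kg.graph.bind("HIPAA", HIPAA)
    for name, parent in schema.classes.items():
        kg.add((HIPAA[name], RDF.type, OWL.Class))
        if parent is not None:
            kg.add((HIPAA[name], RDFS.subClassOf, HIPAA[parent]))
    for a, b in schema.disjoint_pairs():
        kg.add((HIPAA[a], OWL.disjointWith, HIPAA[b]))
    for prop, (dom, rng) in schema.object_properties.items():
        kg.add((HIPAA[prop], RDF.type, OWL.ObjectProperty))
        kg.add((HIPAA[prop], RDFS.domain, HIPAA[dom]))
        kg.add((HIPAA[prop], RDFS.range, HIPAA[rng]))
    return kg


def classify_rule(
    statement: DeonticStatement,
    schema: HipaaOntologySchema,
    rule_keywords: Mapping[str, tuple[str, ...]] | None = None,
) -> str:
    """Map a deontic statement to a CovidRule subclass by keyword, else CovidRule."""
    rule_keywords = DEFAULT_RULE_KEYWORDS if rule_keywords is None else rule_keywords
    text = statement.sentence.lower()
    for subclass, keywords in rule_keywords.items():
        if subclass not in schema.classes:
            raise ValueError(f"rule keyword map names unknown class {subclass!r}")
        if any(kw in text for kw in keywords):
            return subclass
    return "CovidRule"


def populate(
    policy: OrganizationPolicy,
    schema: HipaaOntologySchema,
    kg: KnowledgeGraph | None = None,
    stakeholder_type: str = "Covered_Entities",
    rule_keywords: Mapping[str, tuple[str, ...]] | None = None,
) -> KnowledgeGraph:
    """Populate the HIPAA ontology graph with one organization's rules.

    The organization node is typed by its stakeholder subclass; each
    deontic statement becomes a rule individual linked via
    ``hasCovidRule`` and annotated with its modality (permission or
    obligation) and sentence text.  Populating the same organization
    twice is an error.
    """
    if stakeholder_type not in schema.subclasses_of("Stakeholder"):
        raise ValueError(f"unknown stakeholder type {stakeholder_type!r}")
    if kg is None:
        kg = hipaa_base_graph(schema)
    org = _org_iri(policy.org_id)
    if (org, RDF.type, None) in kg.graph:
        raise ValueError(f"organization {policy.org_id!r} is already populated")
    kg.add((org, RDF.type, HIPAA[stakeholder_type]))
    kg.add((org, RDFS.label, Literal(policy.org_id)))
    for i, statement in enumerate(policy.statements):
        rule = HIPAA[f"{str(org).rsplit('#', 1)[1]}_rule_{i}"]
        subclass = classify_rule(statement, schema, rule_keywords)
        kg.add((rule, RDF.type, HIPAA[subclass]))
        kg.add((rule, MODALITY, Literal(statement.category)))
        kg.add((rule, RULE_TEXT, Literal(statement.sentence)))
        kg.add((org, HIPAA["hasCovidRule"], rule))
    return kg


def assert_coverage(kg: KnowledgeGraph, org_id: str) -> RuleCoverage:
    """SPARQL coverage check: covered or N/A per CovidRule subclass."""
    org = _org_iri(org_id)
    if (org, RDF.type, None) not in kg.graph:
        raise ValueError(f"unknown organization {org_id!r}")
    rows = kg.graph.query(
        """
        SELECT ?type ?text WHERE {
            ?org HIPAA:hasCovidRule ?rule .
            ?rule a ?type .
            ?rule HIPAA:ruleText ?text .
        }
        """,
        initNs={"HIPAA": HIPAA},
        initBindings={"org": org},
    )
    by_type: dict[str, list[str]] = {}
    for type_iri, text in rows:
        name = str(type_iri)[len(str(HIPAA)):]
        by_type.setdefault(name, []).append(str(text))
    subclasses = ["Media_Access", "Contacting_Covid19_Patients",
                  "PHI_To_Law_Enforcement", "Telehealth"]
    entries = {}
    for subclass in subclasses:
        texts = tuple(sorted(by_type.get(subclass, [])))
        entries[subclass] = CoverageEntry("covered" if texts else "N/A", texts)
    return RuleCoverage(entries)


def list_covid_rules(kg: KnowledgeGraph) -> list:
    """All rule individuals typed as CovidRule or one of its subclasses."""
    rows = kg.graph.query(
        """
        SELECT DISTINCT ?rule WHERE {
            ?rule a ?type .
            ?type rdfs:subClassOf* HIPAA:CovidRule .
        }
        """,
        initNs={"HIPAA": HIPAA, "rdfs": RDFS},
    )
    return sorted(
        (r for (r,) in rows if (r, RDF.type, OWL.Class) not in kg.graph),
        key=str,
    )


def build_report(
    policy: OrganizationPolicy,
    kg: KnowledgeGraph,
    hipaa_corpus: Document,
    key_terms: KeyTermProfile,
    embedder: HashingDocEmbedder,
    lexdb: Mapping[str, int],
    taxonomy: VagueTaxonomy | None = None,
    provider: EmbeddingProvider | None = None,
    threshold: float = 0.8,
) -> ComplianceReport:
    """Assemble the four compliance signals for one populated organization."""
    coverage = assert_coverage(kg, policy.org_id)
    frequency = semantic_term_frequency(
        policy.document, key_terms, provider=provider, threshold=threshold
    )
    similarity = doc_similarity(policy.document, hipaa_corpus, embedder)
    vagueness = vagueness_report(policy.document, lexdb, taxonomy)
    return ComplianceReport(policy.org_id, coverage, frequency, similarity, vagueness)
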