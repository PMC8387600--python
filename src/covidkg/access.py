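"""Attribute-based access control over knowledge-graph facts.

A request names a target fact and the requesting user's attributes.  The
decision procedure traces the fact to its data source (the
``Data_Source`` entity sharing the fact's document provenance), compiles
the source's policy rules into attribute predicates (the worked case: a
no-commercial-use rule yields "Is the user a commercial agent?" on the
role attribute and "Does the user intend to share this information for
commercial purposes?" on the purpose attribute), and allows access only
when every predicate passes.  Sources without a policy on record are
denied by default (fail-closed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import RDF, URIRef

from .bkg import KnowledgeGraph, mint_entity_iri
from .compliance import OrganizationPolicy
from .policy_nlp import DeonticStatement
from .schema import BKG


class MissingProvenanceError(LookupError):
    """Raised when a fact has no traceable data source."""


@dataclass
class AccessRequest:
    """User attributes plus a target fact pattern (subject, relation, object)."""

    user_attributes: dict[str, str]
    target: tuple[str, str, str]

    def __post_init__(self) -> None:
        if not self.user_attributes:
            raise ValueError("user attributes must be non-empty")


@dataclass(frozen=True)
class PolicyPredicate:
    """A yes/no question over one request attribute; "yes" values deny."""

    question: str
    attribute: str
    denied_values: frozenset[str]

    def evaluate(self, attributes: dict[str, str]) -> tuple[str, bool]:
        """Return (answer, passed); matching is case-insensitive exact."""
        value = str(attributes.get(self.attribute, "")).casefold().strip()
        hit = value in {v.casefold() for v in self.denied_values}
        return ("Yes" if hit else "No"), not hit


@dataclass
class AccessDecision:
    verdict: str  # "allow" | "deny"
    justification: list[tuple[str, str]] = field(default_factory=list)
    data_source: str | None = None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "justification": [list(j) for j in self.justification],
            "data_source": self.data_source,
        }


#: Restriction keyword → the predicates it compiles to.
DEFAULT_RESTRICTION_PATTERNS: dict[str, tuple[PolicyPredicate, ...]] = {
    "commercial": (
        PolicyPredicate(
            "Is the user a commercial agent?",
            "role",
            frozenset({"commercial agent"}),
        ),
        PolicyPredicate(
            "Does the user intend to share this information for commercial purposes?",
            "purpose",
            frozenset({"commercial", "commercial purposes", "commercial sharing"}),
        ),
    ),
}


def _resolve_term(kg: KnowledgeGraph, term: str | URIRef, predicate: bool = False):
    if isinstance(term, URIRef):
        return term
    return BKG[term] if predicate else mint_entity_iri(term)


def trace_source(kg: KnowledgeGraph, fact: tuple) -> URIRef:
    """Trace a fact to the Data_Source entity behind its document.

    The fact's subject and object carry document provenance annotations;
    the source is the Data_Source-typed entity sharing one of those
    documents.  With several candidates, a source directly linked to one
    of the fact's endpoints wins.  A fact absent from the graph, or one
    whose documents contain no data source, raises
    :class:`MissingProvenanceError`.
    """
    s, p, o = fact
    s = _resolve_term(kg, s)
    p = _resolve_term(kg, p, predicate=True)
    o = _resolve_term(kg, o)
    if (s, p, o) not in kg.graph:
        raise MissingProvenanceError(f"fact {fact!r} is not in the graph")
    papers = kg.paper_ids(s) | kg.paper_ids(o)
    sources = [
        e
        for e in kg.entities_of_class("Data_Source")
        if kg.paper_ids(e) & papers
    ]
    if not sources:
        raise MissingProvenanceError(f"no data source linked to fact {fact!r}")
    if len(sources) > 1:
        linked = [
            e
            for e in sources
            if any(True for _ in kg.graph.predicate_objects(e))
            and ((e, None, s) in kg.graph or (e, None, o) in kg.graph)
        ]
        if len(linked) == 1:
            return linked[0]
    return sources[0]


def compile_predicates(
    rules: list[DeonticStatement],
    patterns: dict[str, tuple[PolicyPredicate, ...]] | None = None,
) -> list[PolicyPredicate]:
    """Compile policy rules into attribute predicates via restriction keywords.

    Rules containing a configured restriction keyword contribute that
    keyword's predicates (deduplicated, order-preserving); other rules
    contribute none.
    """
    patterns = DEFAULT_RESTRICTION_PATTERNS if patterns is None else patterns
    out: list[PolicyPredicate] = []
    for rule in rules:
        text = rule.sentence.lower()
        for keyword, predicates in patterns.items():
            if keyword in text:
                for predicate in predicates:
                    if predicate not in out:
                        out.append(predicate)
    return out


def decide(
    request: AccessRequest,
    kg: KnowledgeGraph,
    policies: dict[str, OrganizationPolicy],
    patterns: dict[str, tuple[PolicyPredicate, ...]] | None = None,
) -> AccessDecision:
    """Decide an access request: trace, compile, evaluate; allow iff all pass.

    ``policies`` maps a data-source label (case-insensitive) to the
    organization policy governing it.  A source with no policy on record
    is denied by default.
    """
    source = trace_source(kg, request.target)
    source_label = kg.label_of(source)
    policy = policies.get(source_label)
    if policy is None:
        by_fold = {k.casefold(): v for k, v in policies.items()}
        policy = by_fold.get(source_label.casefold())
    if policy is None:
        return AccessDecision(
            "deny",
            [("Is a policy on record for this data source?", "No")],
            source_label,
        )
    predicates = compile_predicates(policy.statements, patterns)
    justification: list[tuple[str, str]] = []
    all_pass = True
    for predicate in predicates:
        answer, passed = predicate.evaluate(request.user_attributes)
        justification.append((predicate.question, answer))
        all_pass = all_pass and passed
    return AccessDecision("allow" if all_pass else "deny", justification, source_label)
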