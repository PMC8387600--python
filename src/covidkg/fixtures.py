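"""Deterministic generators for synthetic test inputs.

Every generator is a pure function of its :class:`FixtureSpec` — all
randomness flows through ``numpy.random.default_rng(seed)`` (PCG64), the
single RNG fixed project-wide — and returns exact ground-truth metadata
alongside its output, so every pipeline statistic (modal counts, deontic
categories, vague-term matches, key-term frequencies, planted entities
and relations) can be recovered and checked in closed loop.

The generated language is deliberately synthetic: template sentences
over a curated filler vocabulary that is disjoint from every modal verb,
vague term, key term and entity surface the pipelines look for, so
planted counts are the only signal present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bkg import KnowledgeGraph, assemble
from .ner import AnnotatedDocument, Document, EntityMention, TokenSpan
from .policy_nlp import (
    OBLIGATION_MODALS,
    PERMISSION_MODALS,
    load_vague_taxonomy,
)
from .relext import (
    NO_RELATION,
    CandidatePair,
    EmbeddingProvider,
    RelationAssertion,
    generate_candidates,
)
from .schema import EntityClass, RelationType, SchemaGraph, build_bkg_schema


#: Filler vocabulary for policy-style sentences; disjoint from all modal
#: verbs, vague-taxonomy terms and default planted key terms.
POLICY_FILLERS = (
    "office", "processes", "records", "during", "review", "team",
    "submits", "updates", "clinic", "visits", "archives", "files",
    "checks", "the", "for", "and",
)

#: Filler vocabulary for paper-style sentences; token-disjoint from the
#: default entity inventory.
PAPER_FILLERS = (
    "the", "study", "reported", "that", "clinicians", "observed",
    "among", "admitted", "adults", "over", "weeks", "with",
)

DEFAULT_MODAL_DENSITY = {
    "must": 0.15, "should": 0.10, "may": 0.15, "can": 0.10, "will": 0.10,
}
DEFAULT_VAGUE_DENSITY = {
    "conditional_terms": 0.15,
    "generalization_terms": 0.15,
    "generalizing_numeric_terms": 0.10,
}
DEFAULT_KEYTERM_PLAN = {"telehealth": 12, "provider": 9, "notification": 6}

DEFAULT_ENTITY_INVENTORY = {
    "covid-19": "Disease",
    "influenza": "Disease",
    "remdesivir": "Drug",
    "favipiravir": "Drug",
    "fever": "Symptom",
    "chest pain": "Symptom",
    "oxygen therapy": "Procedure",
    "case registry": "Data_Source",
}
DEFAULT_RELATION_PLAN = (
    ("covid-19", "treats", "remdesivir"),
    ("influenza", "treats", "favipiravir"),
    ("covid-19", "diagnoses", "fever"),
    ("covid-19", "diagnoses", "chest pain"),
    ("case registry", "indicates", "oxygen therapy"),
    ("case registry", "data_collected", "covid-19"),
)


@dataclass
class FixtureSpec:
    """Controls for the corpus generators; all densities are rates in [0, 1]."""

    seed: int = 0
    n_docs: int = 10
    sentences_per_doc: int = 12
    modal_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODAL_DENSITY)
    )
    vague_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VAGUE_DENSITY)
    )
    keyterm_plan: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_KEYTERM_PLAN)
    )
    entity_inventory: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ENTITY_INVENTORY)
    )
    relation_plan: tuple[tuple[str, str, str], ...] = DEFAULT_RELATION_PLAN

    def __post_init__(self) -> None:
        for name, rate in {**self.modal_density, **self.vague_density}.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"density for {name!r} must be in [0, 1]")


def mini_schema() -> SchemaGraph:
    """A fully enumerable 5-class, 4-relation schema with a provenance class."""
    schema = SchemaGraph()
    for name in ("Disease", "Drug", "Symptom", "Procedure"):
        schema.classes[name] = EntityClass(name)
    schema.classes["Data_Source"] = EntityClass("Data_Source", is_custom=True)
    schema.relations["treats"] = RelationType(
        "treats", frozenset({"Disease"}), frozenset({"Drug"})
    )
    schema.relations["diagnoses"] = RelationType(
        "diagnoses", frozenset({"Disease"}), frozenset({"Symptom"})
    )
    schema.relations["indicates"] = RelationType(
        "indicates", frozenset({"Data_Source"}), frozenset({"Procedure"})
    )
    schema.relations["data_collected"] = RelationType(
        "data_collected", frozenset({"Data_Source"}), frozenset({"Disease"})
    )
    schema.validate()
    return schema


def toy_lexdb() -> dict[str, int]:
    """A hand-built word → synset-count lexicon for ambiguity tests."""
    return {
        "bank": 2, "cold": 3, "oxygen": 1, "fever": 1, "mask": 2,
        "record": 2, "patient": 2, "chart": 2, "virus": 1, "clinic": 1,
        "privacy": 1, "policy": 2, "data": 1, "notice": 2, "office": 2,
        "review": 2, "team": 1, "files": 2, "visits": 1, "checks": 2,
    }


def toy_embeddings(dimension: int = 4, seed: int = 7) -> EmbeddingProvider:
    """Seed-deterministic unit vectors over the fixture vocabulary."""
    vocab = set(PAPER_FILLERS) | set(POLICY_FILLERS)
    for surface in DEFAULT_ENTITY_INVENTORY:
        vocab.update(surface.split())
    vocab.update({"doctor", "physician", "telehealth", "provider", "notification"})
    rng = np.random.default_rng(seed)
    vectors = {}
    for word in sorted(vocab):
        v = rng.standard_normal(dimension)
        vectors[word] = v / np.linalg.norm(v)
    return EmbeddingProvider(vectors, dimension)


# ---------------------------------------------------------------------------
# Policy-style corpus


def gen_policy_corpus(spec: FixtureSpec) -> tuple[list[Document], dict]:
    """Generate policy-like documents with exact planted ground truth.

    Each sentence gets at most one modal verb (sampled per-modal by
    ``modal_density``, first hit wins) and at most one vague term per
    taxonomy category in ``vague_density``; key-term occurrences are
    placed by the ``keyterm_plan``.  The returned ground truth records
    modal counts, permission/obligation sentence counts, per-category and
    per-document vague-term matches, key-term counts, per-document word
    token counts, and the filler vocabulary (so callers can extend
    stoplists with it).
    """
    taxonomy = load_vague_taxonomy()
    modal_vague_terms = set(taxonomy.categories.get("modal_verbs", ()))
    for term in spec.keyterm_plan:
        if term in PERMISSION_MODALS | OBLIGATION_MODALS or any(
            term in terms for terms in taxonomy.categories.values()
        ):
            raise ValueError(f"key term {term!r} collides with modal/vague inventory")

    rng = np.random.default_rng(spec.seed)
    modal_counts = {m: 0 for m in sorted(spec.modal_density)}
    vague_counts = {c: 0 for c in sorted(spec.vague_density)}
    keyterm_counts = {t: 0 for t in spec.keyterm_plan}
    gt = {
        "n_permissions": 0,
        "n_obligations": 0,
        "vague_total": 0,
        "doc_word_tokens": {},
        "doc_vague_matches": {},
        "filler_words": sorted(set(POLICY_FILLERS)),
    }

    # pre-place key-term occurrences on (doc, sentence) slots
    placements: dict[tuple[int, int], list[str]] = {}
    for term in sorted(spec.keyterm_plan):
        for _ in range(spec.keyterm_plan[term]):
            slot = (
                int(rng.integers(spec.n_docs)),
                int(rng.integers(spec.sentences_per_doc)),
            )
            placements.setdefault(slot, []).append(term)

    docs = []
    for d in range(spec.n_docs):
        sentences = []
        n_words = 0
        n_vague = 0
        for s in range(spec.sentences_per_doc):
            words = [str(rng.choice(POLICY_FILLERS)) for _ in range(4)]
            modal = None
            for m in sorted(spec.modal_density):
                if rng.random() < spec.modal_density[m]:
                    modal = m
                    break
            if modal is not None:
                words.insert(1, modal)
                modal_counts[modal] += 1
                if modal in PERMISSION_MODALS:
                    gt["n_permissions"] += 1
                elif modal in OBLIGATION_MODALS:
                    gt["n_obligations"] += 1
                if modal in modal_vague_terms:
                    n_vague += 1
                    gt["vague_total"] += 1
            for cat in sorted(spec.vague_density):
                if cat == "modal_verbs" and modal is not None:
                    continue  # keep one modal-ish token per sentence
                if rng.random() < spec.vague_density[cat]:
                    term = str(rng.choice(taxonomy.categories[cat]))
                    words.extend(term.split())
                    vague_counts[cat] += 1
                    n_vague += 1
                    gt["vague_total"] += 1
                    if cat == "modal_verbs":
                        modal = term
                        if term in modal_counts:
                            modal_counts[term] += 1
                        if term in PERMISSION_MODALS:
                            gt["n_permissions"] += 1
                        elif term in OBLIGATION_MODALS:
                            gt["n_obligations"] += 1
            for term in placements.get((d, s), []):
                words.append(term)
                keyterm_counts[term] += 1
            n_words += len(words)
            sentences.append(words[0].capitalize() + " " + " ".join(words[1:]) + ".")
        doc_id = f"policy_{d:03d}"
        docs.append(Document(id=doc_id, text=" ".join(sentences)))
        gt["doc_word_tokens"][doc_id] = n_words
        gt["doc_vague_matches"][doc_id] = n_vague
    gt["modal_counts"] = modal_counts
    gt["vague_counts"] = vague_counts
    gt["keyterm_counts"] = keyterm_counts
    return docs, gt


# ---------------------------------------------------------------------------
# Annotated paper-style corpus


def gen_annotated_corpus(
    spec: FixtureSpec, schema: SchemaGraph | None = None
) -> tuple[list[AnnotatedDocument], list[tuple[CandidatePair, str]], dict]:
    """Generate annotated paper-like documents and labelled relation pairs.

    Every document plants gazetteer entities from the inventory at known
    character offsets (the gold mentions).  Candidate pairs generated
    under the schema are labelled by the relation plan — a pair whose
    (head surface, relation, tail surface) appears in the plan gets that
    relation, every other candidate gets the no-relationship label.
    """
    schema = mini_schema() if schema is None else schema
    for surface, label in spec.entity_inventory.items():
        if label not in schema.classes:
            raise ValueError(f"inventory label {label!r} not present in schema")
    plan = set()
    for head, rel, tail in spec.relation_plan:
        relation = schema.relations.get(rel)
        if relation is None or not relation.admits(
            spec.entity_inventory[head], spec.entity_inventory[tail]
        ):
            raise ValueError(f"planted relation {(head, rel, tail)!r} violates schema")
        plan.add((head, rel, tail))

    rng = np.random.default_rng(spec.seed)
    surfaces = sorted(spec.entity_inventory)
    docs: list[AnnotatedDocument] = []
    labelled: list[tuple[CandidatePair, str]] = []
    planted_relations = {rel: 0 for _, rel, _ in spec.relation_plan}

    for d in range(spec.n_docs):
        parts: list[str] = []
        gold: list[EntityMention] = []
        pos = 0

        def emit(word: str) -> None:
            nonlocal pos
            if parts:
                pos += 1  # joining space
            parts.append(word)
            pos += len(word)

        n_sentences = 3
        for _ in range(n_sentences):
            picked = rng.choice(len(surfaces), size=2, replace=False)
            emit(str(rng.choice(PAPER_FILLERS)).capitalize())
            for k, idx in enumerate(picked):
                surface = surfaces[int(idx)]
                emit(str(rng.choice(PAPER_FILLERS)))
                start = pos + 1 if parts else 0
                emit(surface)
                gold.append(
                    EntityMention(
                        TokenSpan(start, start + len(surface), surface),
                        spec.entity_inventory[surface],
                    )
                )
                if k == 0:
                    emit(str(rng.choice(PAPER_FILLERS)))
            parts[-1] = parts[-1] + "."
            pos += 1
        text = " ".join(parts)
        doc = Document(id=f"paper_{d:03d}", text=text)
        for mention in gold:
            assert text[mention.span.start : mention.span.end] == mention.span.surface
        docs.append(AnnotatedDocument(doc, gold))

        dedup: dict[str, EntityMention] = {}
        for mention in gold:
            dedup.setdefault(mention.span.surface, mention)
        for pair in generate_candidates(list(dedup.values()), schema):
            key = (pair.head.span.surface, None, pair.tail.span.surface)
            label = NO_RELATION
            for rel in pair.allowed:
                if (key[0], rel, key[2]) in plan:
                    label = rel
                    planted_relations[rel] += 1
                    break
            labelled.append((pair, label))

    gt = {
        "inventory": dict(spec.entity_inventory),
        "planted_relation_counts": planted_relations,
        "n_labelled_pairs": len(labelled),
        "filler_words": sorted(set(PAPER_FILLERS)),
    }
    return docs, labelled, gt


def split_corpus(items: list, holdout_fraction: float, seed: int) -> tuple[list, list]:
    """Reproducible disjoint train/held-out split."""
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_test = max(1, int(round(holdout_fraction * len(items))))
    test_idx = set(int(i) for i in order[:n_test])
    train = [x for i, x in enumerate(items) if i not in test_idx]
    test = [x for i, x in enumerate(items) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# Worked example graph


#: The corrected data-source/therapeutic-procedure query (the printed
#: version drops the object variable from its last triple pattern).
WORKED_EXAMPLE_QUERY = """
SELECT ?x ?y WHERE {
    ?x a BKG:Data_Source .
    ?y a BKG:Therapeutic_or_Preventive_Procedure .
    ?x BKG:indicates ?y .
}
"""

_WORKED_ENTITIES = (
    ("COVID-19", "Disease_or_Syndrome"),
    ("remdesevir", "Pharmacologic_Substance"),
    ("hydroxychloroquine", "Pharmacologic_Substance"),
    ("famotidine", "Pharmacologic_Substance"),
    ("non-specific clinical signs", "Sign_or_Symptom"),
    ("chest pain", "Sign_or_Symptom"),
    ("anecdotal report", "Data_Source"),
    ("famotidine treatment", "Therapeutic_or_Preventive_Procedure"),
)

_WORKED_RELATIONS = (
    ("COVID-19", "treats", "remdesevir"),
    ("COVID-19", "treats", "hydroxychloroquine"),
    ("COVID-19", "treats", "famotidine"),
    ("COVID-19", "diagnoses", "non-specific clinical signs"),
    ("COVID-19", "diagnoses", "chest pain"),
    ("anecdotal report", "indicates", "famotidine treatment"),
)


def worked_example_graph() -> KnowledgeGraph:
    """The populated single-paper example graph.

    COVID-19 is typed as a disease; it is linked by ``treats`` to
    remdesevir, hydroxychloroquine and famotidine and by ``diagnoses`` to
    non-specific clinical signs and chest pain; an anecdotal-report data
    source ``indicates`` the famotidine treatment procedure.  Validates
    against the default BKG schema.
    """
    schema = build_bkg_schema()
    pieces = []
    mentions = []
    by_surface = {}
    pos = 0
    for surface, label in _WORKED_ENTITIES:
        if pieces:
            pos += 3  # " ; " separator
        mention = EntityMention(TokenSpan(pos, pos + len(surface), surface), label)
        mentions.append(mention)
        by_surface[surface] = mention
        pieces.append(surface)
        pos += len(surface)
    doc = Document(id="covid_case_report", text=" ; ".join(pieces))
    assertions = [
        RelationAssertion(by_surface[h], rel, by_surface[t], 1.0)
        for h, rel, t in _WORKED_RELATIONS
    ]
    return assemble(mentions, assertions, schema, doc)
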