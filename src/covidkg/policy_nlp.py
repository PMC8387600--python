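"""Text analytics over privacy-policy and regulation documents.

This module covers the policy-side computations of the framework:

* key-term extraction from a regulation corpus (bag of words after
  stopword and modal-verb removal);
* deontic-logic statement (DLS) detection — sentences carrying a modal
  verb, categorized as permissions or obligations by which modal set the
  trigger belongs to;
* semantic key-term frequency in a policy (exact matches plus
  embedding-similar tokens);
* document similarity in radians (the arccosine of the cosine between
  document vectors);
* the vagueness score: the sum of an ambiguous-word ratio (words with
  more than one sense in a lexical database), a vague-term ratio
  (matches against a four-category taxonomy of inherently vague terms),
  and a normalized Dale–Chall reading-complexity component.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import yaml

from .ner import Document, word_tokens
from .relext import EmbeddingProvider, HashingEmbeddingProvider

#: Default modal-verb sets for deontic categorization.  "may" sits in the
#: permission set: permission-style guidance sentences in HIPAA routinely
#: open with it even though it is also an inherently vague term.
PERMISSION_MODALS = frozenset({"will", "can", "could", "may", "might"})
OBLIGATION_MODALS = frozenset({"must", "should", "shall"})

_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st", "vs", "etc", "e.g", "i.e",
    "u.s", "inc", "no", "fig", "al",
}


class ConfigurationError(ValueError):
    """Raised for inconsistent analysis configuration (e.g. overlapping modal sets)."""


# ---------------------------------------------------------------------------
# Packaged resources


def load_stopwords() -> frozenset[str]:
    text = resources.files("covidkg.data").joinpath("stopwords.txt").read_text()
    return frozenset(w for w in text.split() if w)


def load_familiar_words() -> frozenset[str]:
    """Compact familiar-word list for the Dale–Chall component."""
    text = resources.files("covidkg.data").joinpath("familiar_words.txt").read_text()
    return frozenset(w for w in text.split() if w)


@dataclass(frozen=True)
class VagueTaxonomy:
    """Category name → vague-term list; multi-word entries match as phrases."""

    categories: Mapping[str, tuple[str, ...]]

    def all_terms(self) -> list[tuple[tuple[str, ...], str]]:
        """(token tuple, category) for every term, longest terms first."""
        out = []
        for cat, terms in self.categories.items():
            for term in terms:
                out.append((tuple(term.lower().split()), cat))
        out.sort(key=lambda e: -len(e[0]))
        return out


def load_vague_taxonomy() -> VagueTaxonomy:
    text = resources.files("covidkg.data").joinpath("vague_terms.yaml").read_text()
    raw = yaml.safe_load(text)
    return VagueTaxonomy({cat: tuple(terms) for cat, terms in raw.items()})


# ---------------------------------------------------------------------------
# Sentences and key terms


def split_sentences(text: str) -> list[str]:
    """Split on sentence-final punctuation followed by a capitalized start.

    A period after a known abbreviation or a single capital letter
    (initials) does not end a sentence.
    """
    sentences: list[str] = []
    start = 0
    for match in re.finditer(r"[.?!]+(?=\s+[A-Z\"“(])", text):
        end = match.end()
        preceding = text[start:end]
        last_word = re.findall(r"[\w.]+(?=[.?!]+$)", preceding.strip())
        if last_word:
            w = last_word[0].rstrip(".").lower()
            if w in _ABBREVIATIONS or (len(w) == 1 and w.isalpha()):
                continue
        chunk = preceding.strip()
        if chunk:
            sentences.append(chunk)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


@dataclass
class KeyTermProfile:
    """Terms with non-increasing frequencies, stop/modal words excluded."""

    entries: list[tuple[str, int]]

    @property
    def terms(self) -> list[str]:
        return [t for t, _ in self.entries]

    def frequency(self, term: str) -> int:
        for t, f in self.entries:
            if t == term:
                return f
        return 0


def extract_key_terms(
    corpus: list[Document],
    top_k: int = 20,
    stoplist: frozenset[str] | None = None,
    modal_exclusions: frozenset[str] | None = None,
) -> KeyTermProfile:
    """Most frequent content terms across a corpus.

    Tokens are lowercased; stopwords and modal verbs are removed (the
    modals are reserved for deontic rule detection).  Ties at equal
    frequency break alphabetically.
    """
    if top_k < 0:
        raise ValueError("top_k must be non-negative")
    stoplist = load_stopwords() if stoplist is None else stoplist
    if modal_exclusions is None:
        modal_exclusions = PERMISSION_MODALS | OBLIGATION_MODALS
    counts: dict[str, int] = {}
    for doc in corpus:
        for token in word_tokens(doc.text):
            w = token.surface.lower()
            if w in stoplist or w in modal_exclusions or not any(
                c.isalpha() for c in w
            ):
                continue
            counts[w] = counts.get(w, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return KeyTermProfile(ranked[:top_k])


# ---------------------------------------------------------------------------
# Deontic logic statements


@dataclass(frozen=True)
class DeonticStatement:
    """A sentence with its modal trigger and deontic category."""

    sentence: str
    trigger: str
    category: str  # "permission" | "obligation"


def extract_dls(
    doc: Document,
    permission_modals: frozenset[str] = PERMISSION_MODALS,
    obligation_modals: frozenset[str] = OBLIGATION_MODALS,
) -> list[DeonticStatement]:
    """One deontic statement per sentence containing a modal verb.

    The first modal occurring in the sentence is the trigger; its modal
    set fixes the category.  Modal-free sentences are omitted.
    """
    overlap = set(permission_modals) & set(obligation_modals)
    if overlap:
        raise ConfigurationError(
            f"permission and obligation modal sets overlap: {sorted(overlap)}"
        )
    statements = []
    for sentence in split_sentences(doc.text):
        for token in word_tokens(sentence):
            w = token.surface.lower()
            if w in permission_modals:
                statements.append(DeonticStatement(sentence, w, "permission"))
                break
            if w in obligation_modals:
                statements.append(DeonticStatement(sentence, w, "obligation"))
                break
    return statements


def modal_distribution(
    docs: list[Document], modals: frozenset[str] | None = None
) -> dict[str, int]:
    """Token counts over the modal inventory (all zero for an empty corpus)."""
    if modals is None:
        modals = PERMISSION_MODALS | OBLIGATION_MODALS
    counts = {m: 0 for m in sorted(modals)}
    for doc in docs:
        for token in word_tokens(doc.text):
            w = token.surface.lower()
            if w in counts:
                counts[w] += 1
    return counts


# ---------------------------------------------------------------------------
# Semantic key-term frequency and document similarity


def semantic_term_frequency(
    doc: Document,
    key_terms: KeyTermProfile,
    provider: EmbeddingProvider | None = None,
    threshold: float = 0.8,
) -> int:
    """Count tokens that match a key term exactly or semantically.

    Exact (case-insensitive) matches always count.  With an embedding
    provider, a token also counts when its cosine similarity to any key
    term reaches ``threshold``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    term_set = {t.lower() for t in key_terms.terms}
    term_vecs = None
    if provider is not None and term_set:
        vecs = [(t, provider.vector(t)) for t in sorted(term_set)]
        term_vecs = [(t, v / n) for t, v in vecs if (n := np.linalg.norm(v)) > 0]
    count = 0
    for token in word_tokens(doc.text):
        w = token.surface.lower()
        if w in term_set:
            count += 1
            continue
        if term_vecs:
            v = provider.vector(w)
            n = np.linalg.norm(v)
            if n == 0:
                continue
            v = v / n
            if any(float(v @ tv) >= threshold for _, tv in term_vecs):
                count += 1
    return count


@dataclass(frozen=True)
class SimilarityScore:
    """Angular distance between two document vectors, in radians [0, π]."""

    radians: float


class HashingDocEmbedder:
    """Deterministic document embedder: mean of seeded per-word vectors.

    Emulates a fixed, corpus-independent document-vector model; two
    embedders with equal dimension and seed produce identical vectors on
    all platforms.
    """

    def __init__(self, dimension: int = 64, seed: int = 0):
        self.dimension = dimension
        self.seed = seed
        self._provider = HashingEmbeddingProvider(dimension, seed)

    def embed(self, doc: Document) -> np.ndarray:
        tokens = [t.surface.lower() for t in word_tokens(doc.text)]
        if not tokens:
            return np.zeros(self.dimension)
        return np.mean([self._provider.vector(t) for t in tokens], axis=0)


def doc_similarity(
    a: Document, b: Document, doc_embedder: HashingDocEmbedder | Callable
) -> SimilarityScore:
    """Angular similarity score: ``arccos`` of the clamped cosine.

    Identical documents score 0; orthogonal document vectors score π/2.
    A lower score means the documents are semantically closer.
    """
    embed = doc_embedder.embed if hasattr(doc_embedder, "embed") else doc_embedder
    va, vb = np.asarray(embed(a), float), np.asarray(embed(b), float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("document embeds to the zero vector; similarity undefined")
    cos = float(np.clip(va @ vb / (na * nb), -1.0, 1.0))
    return SimilarityScore(radians=math.acos(cos))


# ---------------------------------------------------------------------------
# Vagueness components


@dataclass(frozen=True)
class VaguenessReport:
    """The three vagueness components and their sum (optionally rescaled)."""

    ambiguous_ratio: float
    vague_ratio: float
    reading_complexity: float
    total: float
    rescaled: float | None = None

    def to_dict(self) -> dict:
        d = {
            "ambiguous_ratio": self.ambiguous_ratio,
            "vague_ratio": self.vague_ratio,
            "reading_complexity": self.reading_complexity,
            "total": self.total,
        }
        if self.rescaled is not None:
            d["rescaled"] = self.rescaled
        return d


def ambiguous_ratio(
    doc: Document,
    lexdb: Mapping[str, int],
    stoplist: frozenset[str] | None = None,
) -> float:
    """Fraction of in-lexicon content tokens carrying more than one sense.

    ``lexdb`` maps a word to its synset count.  Content tokens are
    alphabetic tokens outside the stoplist; tokens absent from the
    lexicon are excluded from the denominator (0 when none remain).
    """
    stoplist = load_stopwords() if stoplist is None else stoplist
    found = ambiguous = 0
    for token in word_tokens(doc.text):
        w = token.surface.lower()
        if not w.isalpha() or w in stoplist:
            continue
        senses = lexdb.get(w)
        if senses is None:
            continue
        found += 1
        if senses > 1:
            ambiguous += 1
    return ambiguous / found if found else 0.0


def load_lexdb(path: str | Path) -> dict[str, int]:
    """Load a lexical database as two-column TSV: word <TAB> synset count."""
    db = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        word, count = line.split("\t")
        db[word.lower()] = int(count)
    return db


def vague_ratio(doc: Document, taxonomy: VagueTaxonomy | None = None) -> float:
    """Fraction of word tokens consumed by vague-term matches.

    Taxonomy terms (including multi-word phrases) are matched greedily —
    longest match wins, matches never overlap — against the lowercased
    word-token sequence; the denominator is the word-token count.
    """
    if taxonomy is None:
        taxonomy = load_vague_taxonomy()
    tokens = [t.surface.lower() for t in word_tokens(doc.text)]
    if not tokens:
        return 0.0
    terms = taxonomy.all_terms()
    matches = 0
    i = 0
    while i < len(tokens):
        for term, _cat in terms:
            if tuple(tokens[i : i + len(term)]) == term:
                matches += 1
                i += len(term)
                break
        else:
            i += 1
    return matches / len(tokens)


def count_vague_terms(
    doc: Document, taxonomy: VagueTaxonomy | None = None
) -> dict[str, int]:
    """Per-category vague-term match counts (same matching as :func:`vague_ratio`)."""
    if taxonomy is None:
        taxonomy = load_vague_taxonomy()
    tokens = [t.surface.lower() for t in word_tokens(doc.text)]
    counts = {cat: 0 for cat in taxonomy.categories}
    terms = taxonomy.all_terms()
    i = 0
    while i < len(tokens):
        for term, cat in terms:
            if tuple(tokens[i : i + len(term)]) == term:
                counts[cat] += 1
                i += len(term)
                break
        else:
            i += 1
    return counts


def reading_complexity(
    doc: Document,
    word_list: frozenset[str] | None = None,
    normalized: bool = True,
) -> float:
    """Dale–Chall reading complexity.

    Raw score = 0.1579 · (percent difficult words)
              + 0.0496 · (average sentence length in words),
    plus an adjustment of 3.6365 when difficult words exceed 5%.  A word
    is difficult when it is non-numeric and absent from the familiar-word
    list.  With ``normalized`` (the default, used as the vagueness
    component) the raw score is divided by 10 to bring it onto the scale
    of the other two components; this normalization is a package choice.
    """
    word_list = load_familiar_words() if word_list is None else word_list
    sentences = split_sentences(doc.text)
    words = [t.surface for t in word_tokens(doc.text)]
    if not words or not sentences:
        raise ValueError("document has no words; readability undefined")
    difficult = sum(
        1
        for w in words
        if not w.replace(".", "").replace(",", "").isdigit()
        and w.lower() not in word_list
    )
    pct_difficult = 100.0 * difficult / len(words)
    avg_sentence_len = len(words) / len(sentences)
    raw = 0.1579 * pct_difficult + 0.0496 * avg_sentence_len
    if pct_difficult > 5.0:
        raw += 3.6365
    return raw / 10.0 if normalized else raw


def vagueness_score(ambiguous: float, vague: float, complexity: float) -> float:
    """Aggregate vagueness: the plain sum of the three components."""
    if ambiguous < 0 or vague < 0 or complexity < 0:
        raise ValueError("vagueness components must be non-negative")
    return ambiguous + vague + complexity


def vagueness_report(
    doc: Document,
    lexdb: Mapping[str, int],
    taxonomy: VagueTaxonomy | None = None,
    word_list: frozenset[str] | None = None,
    stoplist: frozenset[str] | None = None,
) -> VaguenessReport:
    """Compute all three components and their aggregate for one document."""
    amb = ambiguous_ratio(doc, lexdb, stoplist)
    vag = vague_ratio(doc, taxonomy)
    comp = reading_complexity(doc, word_list, normalized=True)
    return VaguenessReport(amb, vag, comp, vagueness_score(amb, vag, comp))


def rescale_score(raw: float, corpus_min: float, corpus_max: float) -> float:
    """Affine map of ``[corpus_min, corpus_max]`` onto ``[1, 3]``.

    An optional corpus-level post-step; the per-document totals are
    reported unrescaled by default.
    """
    if corpus_max <= corpus_min:
        raise ValueError("corpus_max must exceed corpus_min")
    return 1.0 + 2.0 * (raw - corpus_min) / (corpus_max - corpus_min)
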