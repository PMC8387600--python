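"""Key terms, deontic statements, similarity, and vagueness components."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from covidkg.ner import Document
from covidkg.policy_nlp import (
    ConfigurationError,
    HashingDocEmbedder,
    KeyTermProfile,
    VagueTaxonomy,
    ambiguous_ratio,
    doc_similarity,
    extract_dls,
    extract_key_terms,
    load_stopwords,
    load_vague_taxonomy,
    modal_distribution,
    reading_complexity,
    rescale_score,
    semantic_term_frequency,
    split_sentences,
    vague_ratio,
    vagueness_score,
)
from covidkg.relext import EmbeddingProvider

PERMISSION_SENTENCE = (
    "A covered entity may disclose PHI to a first responder who may have been "
    "exposed to COVID-19, or may otherwise be at risk of contracting or "
    "spreading COVID-19, if the covered entity is authorized by law, such as "
    "state law, to notify persons as necessary in the conduct of a public "
    "health intervention or investigation"
)
OBLIGATION_SENTENCE = (
    "The covered entity must make reasonable efforts to limit the use or "
    "disclosure of PHI to the minimum necessary to accomplish the intended "
    "purpose of the use or disclosure"
)


class TestKeyTerms:
    def test_modal_only_corpus_yields_nothing(self):
        docs = [Document("d", "must should can")]
        assert extract_key_terms(docs, top_k=10).entries == []

    def test_empty_corpus(self):
        assert extract_key_terms([], top_k=10).entries == []

    def test_planted_counts_recovered(self, policy_corpus):
        docs, gt = policy_corpus
        stop = frozenset(load_stopwords() | set(gt["filler_words"]))
        profile = extract_key_terms(docs, top_k=50, stoplist=stop)
        for term, count in gt["keyterm_counts"].items():
            assert profile.frequency(term) == count

    def test_frequencies_non_increasing_and_order_invariant(self, policy_corpus):
        docs, _ = policy_corpus
        a = extract_key_terms(docs, top_k=30)
        b = extract_key_terms(list(reversed(docs)), top_k=30)
        assert a.entries == b.entries
        freqs = [f for _, f in a.entries]
        assert freqs == sorted(freqs, reverse=True)


class TestDeonticStatements:
    def test_hipaa_permission_example(self):
        statements = extract_dls(Document("d", PERMISSION_SENTENCE))
        assert len(statements) == 1
        assert statements[0].category == "permission"
        assert statements[0].trigger == "may"

    def test_hipaa_obligation_example(self):
        statements = extract_dls(Document("d", OBLIGATION_SENTENCE))
        assert len(statements) == 1
        assert statements[0].category == "obligation"
        assert statements[0].trigger == "must"

    def test_modal_free_sentence_omitted(self):
        assert extract_dls(Document("d", "This policy describes our practices.")) == []

    def test_overlapping_modal_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            extract_dls(
                Document("d", "x"),
                permission_modals=frozenset({"may"}),
                obligation_modals=frozenset({"may", "must"}),
            )

    def test_partition_is_exhaustive_over_modal_sentences(self, policy_corpus):
        docs, gt = policy_corpus
        n_perm = n_obl = 0
        for doc in docs:
            for statement in extract_dls(doc):
                assert statement.trigger in statement.sentence.lower()
                if statement.category == "permission":
                    n_perm += 1
                else:
                    n_obl += 1
        assert (n_perm, n_obl) == (gt["n_permissions"], gt["n_obligations"])


class TestModalDistribution:
    def test_empty_corpus_all_zero(self):
        assert all(v == 0 for v in modal_distribution([]).values())

    def test_planted_counts_recovered(self, policy_corpus):
        docs, gt = policy_corpus
        dist = modal_distribution(docs)
        for modal, count in gt["modal_counts"].items():
            assert dist[modal] == count

    def test_counts_conserve_modal_tokens(self, policy_corpus):
        docs, _ = policy_corpus
        dist = modal_distribution(docs)
        brute = sum(
            1
            for doc in docs
            for word in doc.text.lower().replace(".", " ").split()
            if word in dist
        )
        assert sum(dist.values()) == brute


class TestSemanticTermFrequency:
    def test_exact_matches_count_without_embeddings(self):
        profile = KeyTermProfile([("telehealth", 3)])
        doc = Document("d", "Telehealth visits use telehealth tools for telehealth.")
        assert semantic_term_frequency(doc, profile, threshold=1.0) == 3

    def test_empty_document(self):
        assert semantic_term_frequency(Document("d", ""), KeyTermProfile([("x", 1)])) == 0

    def test_semantically_close_token_counts(self):
        v = np.zeros(4); v[0] = 1.0
        w = np.array([0.9, math.sqrt(1 - 0.81), 0.0, 0.0])  # cos = 0.9
        provider = EmbeddingProvider({"doctor": v, "physician": w}, 4)
        profile = KeyTermProfile([("doctor", 5)])
        doc = Document("d", "doctor physician nurse")
        assert semantic_term_frequency(doc, profile, provider, threshold=0.8) == 2


class TestDocSimilarity:
    def test_identical_documents_score_zero(self):
        embedder = HashingDocEmbedder(32, 0)
        doc = Document("d", "privacy policy for patients")
        assert doc_similarity(doc, doc, embedder).radians == pytest.approx(0.0)

    def test_orthogonal_vectors_score_half_pi(self):
        def embed(doc):
            return np.array([1.0, 0.0]) if doc.id == "a" else np.array([0.0, 1.0])

        score = doc_similarity(Document("a", "x"), Document("b", "y"), embed)
        assert score.radians == pytest.approx(math.pi / 2)

    def test_matches_vector_level_recomputation(self):
        embedder = HashingDocEmbedder(32, 3)
        a = Document("a", "the clinic stores patient records")
        b = Document("b", "records retention policy for the clinic")
        got = doc_similarity(a, b, embedder).radians
        va, vb = embedder.embed(a), embedder.embed(b)
        want = math.acos(
            float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
        )
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_vector_rejected(self):
        def embed(doc):
            return np.zeros(4)

        with pytest.raises(ValueError, match="zero"):
            doc_similarity(Document("a", "x"), Document("b", "y"), embed)

    @given(st.text(alphabet="abcdef ", min_size=1), st.text(alphabet="abcdef ", min_size=1))
    def test_symmetry_and_range(self, ta, tb):
        if not ta.strip() or not tb.strip():
            return
        embedder = HashingDocEmbedder(16, 0)
        a, b = Document("a", ta), Document("b", tb)
        sab = doc_similarity(a, b, embedder).radians
        sba = doc_similarity(b, a, embedder).radians
        assert sab == sba
        assert 0.0 <= sab <= math.pi


class TestAmbiguity:
    def test_tokens_absent_from_lexdb_give_zero(self, lexdb):
        assert ambiguous_ratio(Document("d", "zyzzyva qwerty"), lexdb) == 0.0

    def test_half_ambiguous(self, lexdb):
        # "bank" has 2 synsets, "oxygen" has 1
        assert ambiguous_ratio(Document("d", "bank oxygen"), lexdb) == 0.5

    def test_bounds(self, lexdb, policy_corpus):
        docs, _ = policy_corpus
        for doc in docs:
            assert 0.0 <= ambiguous_ratio(doc, lexdb) <= 1.0


class TestVagueRatio:
    def test_worked_sentence(self):
        # matches: "may" (modal), "as needed" (conditional) over 6 word tokens
        doc = Document("d", "We may disclose data as needed.")
        assert vague_ratio(doc) == pytest.approx(2 / 6)

    def test_no_vague_terms(self):
        assert vague_ratio(Document("d", "The clinic stores records.")) == 0.0

    def test_default_taxonomy_contains_modal_may(self):
        taxonomy = load_vague_taxonomy()
        assert "may" in taxonomy.categories["modal_verbs"]
        assert vague_ratio(Document("d", "may"), taxonomy) == 1.0

    def test_longest_match_wins(self):
        taxonomy = VagueTaxonomy({"c": ("as needed",), "m": ("needed",)})
        # "as needed" must consume both tokens as one match
        assert vague_ratio(Document("d", "as needed"), taxonomy) == pytest.approx(0.5)

    def test_planted_matches_recovered(self, policy_corpus):
        docs, gt = policy_corpus
        for doc in docs:
            matches = round(vague_ratio(doc) * gt["doc_word_tokens"][doc.id])
            assert matches == gt["doc_vague_matches"][doc.id]


class TestReadingComplexity:
    def test_ten_familiar_words_single_sentence(self):
        doc = Document("d", "the cat and dog play in the big green garden")
        raw = reading_complexity(doc, normalized=False)
        assert raw == pytest.approx(0.0496 * 10)

    def test_difficult_word_adjustment(self):
        familiar = frozenset({"the"})
        doc = Document("d", "the chromatography")
        raw = reading_complexity(doc, word_list=familiar, normalized=False)
        assert raw == pytest.approx(0.1579 * 50 + 0.0496 * 2 + 3.6365)

    def test_monotone_in_difficult_fraction(self):
        familiar = frozenset({"aa", "bb", "cc", "dd", "ee", "ff", "gg", "hh", "ii", "jj"})
        words = ["aa", "bb", "cc", "dd", "ee", "ff", "gg", "hh", "ii", "jj"]
        scores = []
        for k in range(0, 11, 2):
            text = " ".join(["zz"] * k + words[k:]) if k <= 10 else ""
            scores.append(
                reading_complexity(Document("d", text), familiar, normalized=False)
            )
        assert scores == sorted(scores)

    def test_empty_document_rejected(self):
        with pytest.raises(ValueError):
            reading_complexity(Document("d", "   "))


class TestVaguenessScore:
    def test_zero_components(self):
        assert vagueness_score(0, 0, 0) == 0.0

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            vagueness_score(-0.1, 0, 0)

    def test_rescale_endpoints_and_midpoint(self):
        assert rescale_score(0.7, 0.7, 2.4) == pytest.approx(1.0)
        assert rescale_score(2.4, 0.7, 2.4) == pytest.approx(3.0)
        assert rescale_score(1.55, 0.7, 2.4) == pytest.approx(2.0)

    def test_rescale_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            rescale_score(1.0, 2.0, 2.0)


class TestSentences:
    def test_basic_split(self):
        text = "First rule here. Second rule follows! Third?"
        assert len(split_sentences(text)) == 3

    def test_abbreviation_guard(self):
        text = "Dr. Smith approved the policy. It applies now."
        assert len(split_sentences(text)) == 2
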