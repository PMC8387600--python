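"""Candidate generation, pair embedding, and relation classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from covidkg.fixtures import mini_schema, split_corpus, toy_embeddings
from covidkg.ner import EntityMention, TokenSpan
from covidkg.relext import (
    NO_RELATION,
    CandidatePair,
    EmbeddingProvider,
    RelationClassifier,
    build_classifier,
    classify,
    embed_pair,
    generate_candidates,
    train_classifier,
)
from covidkg.schema import build_bkg_schema


def _mention(surface, label, start=0):
    return EntityMention(TokenSpan(start, start + len(surface), surface), label)


LABELS = ["Disease", "Drug", "Symptom", "Procedure", "Data_Source"]


class TestCandidates:
    def test_incompatible_labels_filtered_out(self, small_schema):
        mentions = [_mention("a", "Drug"), _mention("b", "Symptom", 10)]
        assert generate_candidates(mentions, small_schema) == []

    def test_single_mention_yields_no_pairs(self, small_schema):
        assert generate_candidates([_mention("a", "Disease")], small_schema) == []

    def test_unknown_label_rejected(self, small_schema):
        with pytest.raises(ValueError, match="Mystery"):
            generate_candidates([_mention("a", "Mystery")] * 2, small_schema)

    def test_allowed_set_is_exact(self, small_schema):
        mentions = [_mention("covid-19", "Disease"), _mention("remdesivir", "Drug", 10)]
        pairs = generate_candidates(mentions, small_schema)
        assert len(pairs) == 1
        assert pairs[0].allowed == ("treats",)

    @given(st.lists(st.sampled_from(LABELS), min_size=0, max_size=8))
    def test_matches_brute_force_oracle(self, labels):
        schema = mini_schema()
        mentions = [_mention(f"e{i}", lab, 10 * i) for i, lab in enumerate(labels)]
        got = {
            (p.head.span.surface, p.tail.span.surface, p.allowed)
            for p in generate_candidates(mentions, schema)
        }
        want = set()
        for i, h in enumerate(mentions):
            for j, t in enumerate(mentions):
                if i == j:
                    continue
                allowed = tuple(
                    r.name
                    for r in schema.relations.values()
                    if h.label in r.domain and t.label in r.range
                )
                if allowed:
                    want.add((h.span.surface, t.span.surface, allowed))
        assert got == want


class TestEmbedding:
    def test_pair_vector_has_twice_provider_dimension(self, embeddings8):
        pair = CandidatePair(_mention("covid-19", "Disease"),
                             _mention("fever", "Symptom", 10), ("diagnoses",))
        assert embed_pair(pair, embeddings8).shape == (16,)

    def test_default_dimension_gives_400(self):
        provider = EmbeddingProvider({}, 200)
        pair = CandidatePair(_mention("a", "Disease"), _mention("b", "Drug", 5), ("treats",))
        assert embed_pair(pair, provider).shape == (400,)

    def test_oov_surfaces_embed_to_zero(self):
        provider = EmbeddingProvider({"known": np.ones(4)}, 4)
        pair = CandidatePair(
            _mention("zzz", "Disease"), _mention("qqq", "Drug", 5), ("treats",)
        )
        assert not embed_pair(pair, provider).any()

    def test_multiword_surface_is_mean_of_word_vectors(self, embeddings8):
        pair = CandidatePair(
            _mention("chest pain", "Symptom"), _mention("fever", "Symptom", 20),
            ("co_occurs",),
        )
        vec = embed_pair(pair, embeddings8)
        expected = (embeddings8.vector("chest") + embeddings8.vector("pain")) / 2
        np.testing.assert_allclose(vec[:8], expected)


class TestClassifierArchitecture:
    def test_default_schema_dims(self):
        schema = build_bkg_schema()
        clf = RelationClassifier(schema, 200, seed=0)
        assert clf.layer_dims == [400, 200, 100, 100, 47]

    def test_mini_schema_dims_follow_formula(self, small_schema, embeddings8):
        clf = build_classifier(small_schema, embeddings8, seed=0)
        assert clf.layer_dims == [16, 200, 100, 100, 5]

    def test_same_seed_gives_identical_weights(self, small_schema, embeddings8):
        a = build_classifier(small_schema, embeddings8, seed=3)
        b = build_classifier(small_schema, embeddings8, seed=3)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_dimension_mismatch_rejected(self, small_schema, embeddings8):
        clf = build_classifier(small_schema, embeddings8, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            clf.probabilities(np.zeros(10))


class TestClassify:
    def test_probabilities_sum_to_one(self, small_schema, embeddings8):
        clf = build_classifier(small_schema, embeddings8, seed=0)
        x = embeddings8.vector("fever")
        probs = clf.probabilities(np.concatenate([x, x]))
        assert abs(probs.sum() - 1.0) < 1e-9

    def test_masked_output_restricted_to_allowed(self, small_schema, embeddings8):
        clf = build_classifier(small_schema, embeddings8, seed=0)
        pair = CandidatePair(
            _mention("covid-19", "Disease"), _mention("remdesivir", "Drug", 10),
            ("treats",),
        )
        for seed in range(5):
            clf2 = build_classifier(small_schema, embeddings8, seed=seed)
            out = classify(pair, clf2, embeddings8, threshold=0.0)
            assert out.relation in {"treats", NO_RELATION}
            assert 0.0 <= out.score <= 1.0


class TestTraining:
    def test_zero_epochs_leaves_classifier_unchanged(self, small_schema, embeddings8, annotated_corpus):
        _, pairs, _ = annotated_corpus
        clf = build_classifier(small_schema, embeddings8, seed=0)
        before = [w.copy() for w in clf.weights]
        train_classifier(pairs[:20], clf, embeddings8, epochs=0)
        for w0, w1 in zip(before, clf.weights):
            np.testing.assert_array_equal(w0, w1)

    def test_empty_training_set_rejected(self, small_schema, embeddings8):
        clf = build_classifier(small_schema, embeddings8, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_classifier([], clf, embeddings8)

    def test_training_is_seed_deterministic(self, small_schema, embeddings8, annotated_corpus):
        _, pairs, _ = annotated_corpus
        losses = []
        for _ in range(2):
            clf = build_classifier(small_schema, embeddings8, seed=7)
            train_classifier(pairs[:50], clf, embeddings8, epochs=10, seed=7)
            losses.append(clf.training_loss_[-1])
        assert losses[0] == losses[1]

    def test_loss_non_increasing_within_tolerance(self, small_schema, embeddings8, annotated_corpus):
        _, pairs, _ = annotated_corpus
        clf = build_classifier(small_schema, embeddings8, seed=7)
        train_classifier(pairs, clf, embeddings8, epochs=30, seed=7)
        for prev, nxt in zip(clf.training_loss_, clf.training_loss_[1:]):
            assert nxt <= prev + 1e-3

    def test_separable_training_accuracy(self, small_schema, embeddings8, annotated_corpus):
        _, pairs, _ = annotated_corpus
        clf = build_classifier(small_schema, embeddings8, seed=7)
        train_classifier(pairs, clf, embeddings8, epochs=200, seed=7)
        correct = sum(
            classify(p, clf, embeddings8, threshold=0.0).relation == label
            for p, label in pairs
        )
        assert correct / len(pairs) >= 0.95
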