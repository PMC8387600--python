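"""Schema-constrained relation extraction between typed entity mentions.

Candidate entity pairs are generated only where the schema declares at
least one relation whose domain admits the head label and whose range
admits the tail label.  Each candidate is embedded as the concatenation
of the two entity phrase embeddings (2·d dimensions, 400 by default) and
classified by a four-layer feedforward network with hidden sizes
200/100/100 and a softmax over the schema's R relations plus an explicit
"no relationship" class (47-way for the default 46-relation schema).
At inference, probability mass on relations the schema disallows for the
pair is masked to zero and the distribution renormalized.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ner import EntityMention, word_tokens
from .schema import SchemaGraph

#: Label of the explicit "no relationship" class (always the last softmax index).
NO_RELATION = "NO_RELATION"

HIDDEN_DIMS = (200, 100, 100)
DEFAULT_EMBED_DIM = 200


class EmbeddingProvider:
    """Word-vector lookup with a fixed dimension; OOV words map to zeros.

    Phrase embedding is the unweighted mean of the word vectors of the
    phrase's tokens (so a fully out-of-vocabulary phrase embeds to the
    zero vector).
    """

    def __init__(self, vectors: dict[str, np.ndarray], dimension: int):
        self.dimension = int(dimension)
        self.vectors = {}
        for word, vec in vectors.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {word!r} has length {arr.shape}, expected {dimension}"
                )
            self.vectors[word] = arr

    def vector(self, word: str) -> np.ndarray:
        hit = self.vectors.get(word)
        if hit is None:
            hit = self.vectors.get(word.lower())
        return hit if hit is not None else np.zeros(self.dimension)

    def embed_phrase(self, surface: str) -> np.ndarray:
        tokens = [t.surface for t in word_tokens(surface)]
        if not tokens:
            return np.zeros(self.dimension)
        return np.mean([self.vector(t) for t in tokens], axis=0)

    @classmethod
    def from_text(cls, path: str | Path) -> "EmbeddingProvider":
        """Load the standard text vector format: ``word v1 v2 ... vd`` per line."""
        vectors: dict[str, np.ndarray] = {}
        dimension = None
        for line in Path(path).read_text().splitlines():
            parts = line.rstrip().split(" ")
            if len(parts) == 2 and dimension is None:
                # optional "<count> <dim>" header
                dimension = int(parts[1])
                continue
            if len(parts) < 2:
                continue
            vec = np.array([float(x) for x in parts[1:]])
            if dimension is None:
                dimension = len(vec)
            vectors[parts[0]] = vec
        if dimension is None:
            raise ValueError(f"no vectors found in {path}")
        return cls(vectors, dimension)


class HashingEmbeddingProvider(EmbeddingProvider):
    """Deterministic full-vocabulary provider: each word hashes to a vector.

    A per-word RNG stream is seeded from a BLAKE2 digest of the word and
    the provider seed, so tables are identical across platforms and runs.
    No word is out-of-vocabulary by construction.
    """

    def __init__(self, dimension: int = DEFAULT_EMBED_DIM, seed: int = 0):
        super().__init__({}, dimension)
        self.seed = int(seed)

    def vector(self, word: str) -> np.ndarray:
        key = word.lower()
        cached = self.vectors.get(key)
        if cached is None:
            digest = hashlib.blake2b(
                f"{self.seed}|{key}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dimension)
            cached = self.vectors[key] = vec / np.linalg.norm(vec)
        return cached


@dataclass(frozen=True)
class CandidatePair:
    """An ordered (head, tail) mention pair with its schema-allowed relations."""

    head: EntityMention
    tail: EntityMention
    allowed: tuple[str, ...]


@dataclass(frozen=True)
class RelationAssertion:
    head: EntityMention
    relation: str
    tail: EntityMention
    score: float


def generate_candidates(
    mentions: list[EntityMention], schema: SchemaGraph
) -> list[CandidatePair]:
    """All ordered mention pairs admitting at least one schema relation.

    Pairs whose label pair matches no relation's domain/range are
    discarded; surviving pairs carry the full set of admissible relation
    names in schema declaration order.
    """
    for m in mentions:
        if m.label not in schema.classes:
            raise ValueError(f"mention label {m.label!r} not present in schema")
    pairs = []
    for i, head in enumerate(mentions):
        for j, tail in enumerate(mentions):
            if i == j:
                continue
            allowed = tuple(schema.relations_admitting(head.label, tail.label))
            if allowed:
                pairs.append(CandidatePair(head, tail, allowed))
    return pairs


def embed_pair(pair: CandidatePair, provider: EmbeddingProvider) -> np.ndarray:
    """Concatenate head and tail phrase embeddings into a 2·d input vector."""
    if provider.dimension <= 0:
        raise ValueError("provider dimension must be positive")
    return np.concatenate(
        [provider.embed_phrase(pair.head.span.surface),
         provider.embed_phrase(pair.tail.span.surface)]
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class RelationClassifier:
    """Four-layer feedforward relation classifier.

    Layer dimensions are ``[2·d, 200, 100, 100, R + 1]`` where ``d`` is
    the embedding dimension and ``R`` the schema relation count; the last
    output class is "no relationship".  Hidden activations are ReLU.
    Weight initialization is He-scaled and seed-deterministic.
    """

    def __init__(self, schema: SchemaGraph, embed_dim: int, seed: int = 0):
        self.relation_names = schema.relation_order()
        self.seed = int(seed)
        n_out = len(self.relation_names) + 1
        self.layer_dims = [2 * embed_dim, *HIDDEN_DIMS, n_out]
        rng = np.random.default_rng(self.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(self.layer_dims[:-1], self.layer_dims[1:]):
            self.weights.append(rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in))
            self.biases.append(np.zeros(d_out))

    @property
    def relation_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.relation_names)}

    @property
    def no_relation_index(self) -> int:
        return len(self.relation_names)

    def _forward(self, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        if x.shape[-1] != self.layer_dims[0]:
            raise ValueError(
                f"input dimension {x.shape[-1]} does not match "
                f"classifier input {self.layer_dims[0]}"
            )
        activations = [x]
        h = x
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if k < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
            activations.append(h)
        return activations, h

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        _, logits = self._forward(x)
        return _softmax(logits)


def build_classifier(
    schema: SchemaGraph,
    provider: EmbeddingProvider,
    seed: int = 0,
) -> RelationClassifier:
    """Instantiate the classifier for a schema/embedding pairing."""
    return RelationClassifier(schema, provider.dimension, seed=seed)


def classify(
    pair: CandidatePair,
    classifier: RelationClassifier,
    provider: EmbeddingProvider,
    threshold: float = 0.5,
    mask_renormalize: bool = True,
) -> RelationAssertion:
    """Classify a candidate pair under the schema constraint.

    The full softmax is restricted to the pair's allowed relations plus
    the no-relationship class: disallowed classes get probability zero
    and, with ``mask_renormalize`` (the default), the remaining mass is
    renormalized.  The argmax is returned, with ties broken by schema
    declaration order; a winning relation whose probability falls below
    ``threshold`` is demoted to no-relationship.
    """
    x = embed_pair(pair, provider)
    probs = classifier.probabilities(x)
    index = classifier.relation_index
    keep = np.zeros_like(probs, dtype=bool)
    keep[classifier.no_relation_index] = True
    for name in pair.allowed:
        if name in index:
            keep[index[name]] = True
    masked = np.where(keep, probs, 0.0)
    total = masked.sum()
    if mask_renormalize and total > 0:
        masked = masked / total
    best = int(masked.argmax())
    if best == classifier.no_relation_index:
        return RelationAssertion(pair.head, NO_RELATION, pair.tail, float(masked[best]))
    if masked[best] < threshold:
        return RelationAssertion(
            pair.head, NO_RELATION, pair.tail,
            float(masked[classifier.no_relation_index]),
        )
    return RelationAssertion(
        pair.head, classifier.relation_names[best], pair.tail, float(masked[best])
    )


def train_classifier(
    pairs: list[tuple[CandidatePair, str]],
    classifier: RelationClassifier,
    provider: EmbeddingProvider,
    epochs: int = 200,
    learning_rate: float = 0.01,
    seed: int = 0,
) -> RelationClassifier:
    """Train by per-sample SGD on the cross-entropy of the full softmax.

    Labels must be relation names allowed for their pair, or
    :data:`NO_RELATION`.  Sample order is reshuffled each epoch with a
    seeded generator, so training is fully deterministic.  Mean epoch
    losses are recorded on ``classifier.training_loss_``.
    """
    if not pairs:
        raise ValueError("training set is empty")
    index = classifier.relation_index
    xs, ys = [], []
    for pair, label in pairs:
        if label == NO_RELATION:
            ys.append(classifier.no_relation_index)
        elif label in index and label in pair.allowed:
            ys.append(index[label])
        else:
            raise ValueError(
                f"label {label!r} is not allowed for pair "
                f"({pair.head.span.surface!r}, {pair.tail.span.surface!r})"
            )
        xs.append(embed_pair(pair, provider))
    X = np.vstack(xs)
    y = np.array(ys)

    rng = np.random.default_rng(seed)
    losses: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(y))
        epoch_loss = 0.0
        for idx in order:
            activations, logits = classifier._forward(X[idx])
            probs = _softmax(logits)
            epoch_loss -= float(np.log(max(probs[y[idx]], 1e-300)))
            delta = probs.copy()
            delta[y[idx]] -= 1.0
            for k in range(len(classifier.weights) - 1, -1, -1):
                a = activations[k]
                grad_w = np.outer(a, delta)
                grad_b = delta
                if k > 0:
                    delta = (classifier.weights[k] @ delta) * (activations[k] > 0)
                classifier.weights[k] -= learning_rate * grad_w
                classifier.biases[k] -= learning_rate * grad_b
        losses.append(epoch_loss / len(y))
    classifier.training_loss_ = losses
    return classifier
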