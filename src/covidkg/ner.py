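"""Token-level entity tagging of research-paper text against the BKG classes.

Two interchangeable taggers implement the same ``tag(document)`` surface:

* :class:`GazetteerModel` — deterministic dictionary tagging with
  longest-match, leftmost-first resolution.  Entries containing digits or
  hyphens (``COVID-19``) match case-sensitively, all others
  case-insensitively.
* :class:`CrfTagger` — a linear-chain conditional random field over BIO
  tag sequences, trained by L-BFGS on the L2-penalized conditional
  log-likelihood and decoded with Viterbi under BIO transition
  constraints.

Character offsets are 0-based and half-open throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .schema import SchemaGraph

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['\-][A-Za-z0-9]+)*|[^\sA-Za-z0-9]")


@dataclass
class Document:
    """A plain-text document with a corpus-unique id and free-form metadata."""

    id: str
    text: str
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TokenSpan:
    """A half-open character span ``[start, end)`` with its surface text."""

    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class EntityMention:
    """A typed span: ``label`` names an entity class in the active schema."""

    span: TokenSpan
    label: str
    score: float = 1.0


@dataclass
class AnnotatedDocument:
    document: Document
    gold: list[EntityMention] = field(default_factory=list)


def tokenize(text: str) -> list[TokenSpan]:
    """Split text into word and punctuation spans.

    Words are maximal alphanumeric runs, keeping internal hyphens and
    apostrophes (so ``COVID-19`` is one token); every other non-space
    character is its own token.  Spans are ordered, non-overlapping, and
    cover all non-whitespace characters.
    """
    return [
        TokenSpan(m.start(), m.end(), m.group(0)) for m in _TOKEN_RE.finditer(text)
    ]


def word_tokens(text: str) -> list[TokenSpan]:
    """Tokens that contain at least one alphanumeric character."""
    return [t for t in tokenize(text) if any(c.isalnum() for c in t.surface)]


# ---------------------------------------------------------------------------
# Gazetteer tagging


def _case_sensitive(entry: str) -> bool:
    return any(c.isdigit() for c in entry) or "-" in entry


class GazetteerModel:
    """Dictionary tagger mapping entity surfaces to schema class labels."""

    def __init__(self, entries: dict[str, str], schema: SchemaGraph | None = None):
        if schema is not None:
            for surface, label in entries.items():
                if label not in schema.classes:
                    raise ValueError(
                        f"gazetteer entry {surface!r} has label {label!r} "
                        "not present in schema"
                    )
        self.entries = dict(entries)
        # token-sequence keys: (token_surfaces, case_sensitive) -> label
        self._by_tokens: dict[tuple[str, ...], tuple[str, str]] = {}
        self._max_len = 0
        for surface, label in self.entries.items():
            toks = tuple(t.surface for t in tokenize(surface))
            if not toks:
                continue
            key = toks if _case_sensitive(surface) else tuple(t.lower() for t in toks)
            self._by_tokens[key] = (surface, label)
            self._max_len = max(self._max_len, len(toks))

    def _match(self, tokens: list[TokenSpan], i: int, length: int) -> str | None:
        window = tuple(t.surface for t in tokens[i : i + length])
        hit = self._by_tokens.get(window)
        if hit is not None and _case_sensitive(hit[0]):
            return hit[1]
        hit = self._by_tokens.get(tuple(t.lower() for t in window))
        if hit is not None and not _case_sensitive(hit[0]):
            return hit[1]
        return None

    def tag(self, doc: Document) -> list[EntityMention]:
        """Longest-match, leftmost-first gazetteer tagging."""
        tokens = tokenize(doc.text)
        mentions: list[EntityMention] = []
        i = 0
        while i < len(tokens):
            matched = False
            for length in range(min(self._max_len, len(tokens) - i), 0, -1):
                label = self._match(tokens, i, length)
                if label is not None:
                    start = tokens[i].start
                    end = tokens[i + length - 1].end
                    mentions.append(
                        EntityMention(
                            TokenSpan(start, end, doc.text[start:end]), label, 1.0
                        )
                    )
                    i += length
                    matched = True
                    break
            if not matched:
                i += 1
        return mentions


def tag_entities(doc: Document, model) -> list[EntityMention]:
    """Tag a document with any model exposing ``tag``; mentions sorted by start."""
    mentions = model.tag(doc)
    return sorted(mentions, key=lambda m: (m.span.start, m.span.end))


# ---------------------------------------------------------------------------
# Linear-chain CRF


def _token_features(tokens: list[str], i: int) -> list[str]:
    w = tokens[i]
    feats = [
        "bias",
        f"w={w}",
        f"low={w.lower()}",
        f"suf3={w[-3:].lower()}",
        f"pre2={w[:2].lower()}",
        f"shape={'d' if w.isdigit() else 'X' if w.isupper() else 'Xx' if w[:1].isupper() else 'x'}",
        f"hyph={'-' in w}",
        f"digit={any(c.isdigit() for c in w)}",
    ]
    feats.append(f"prev={tokens[i - 1].lower()}" if i > 0 else "prev=<s>")
    feats.append(f"next={tokens[i + 1].lower()}" if i + 1 < len(tokens) else "next=</s>")
    return feats


def _bio_encode(doc: AnnotatedDocument) -> tuple[list[TokenSpan], list[str]]:
    tokens = tokenize(doc.document.text)
    labels = ["O"] * len(tokens)
    for mention in sorted(doc.gold, key=lambda m: m.span.start):
        inside = [
            k
            for k, t in enumerate(tokens)
            if t.start >= mention.span.start and t.end <= mention.span.end
        ]
        for j, k in enumerate(inside):
            labels[k] = ("B-" if j == 0 else "I-") + mention.label
    return tokens, labels


def bio_to_mentions(
    text: str, tokens: list[TokenSpan], labels: list[str], scores=None
) -> list[EntityMention]:
    """Merge a BIO label sequence into non-overlapping entity mentions."""
    mentions: list[EntityMention] = []
    i = 0
    while i < len(tokens):
        tag = labels[i]
        if tag.startswith("B-"):
            label = tag[2:]
            j = i + 1
            while j < len(tokens) and labels[j] == "I-" + label:
                j += 1
            start, end = tokens[i].start, tokens[j - 1].end
            score = float(np.mean(scores[i:j])) if scores is not None else 1.0
            mentions.append(
                EntityMention(TokenSpan(start, end, text[start:end]), label, score)
            )
            i = j
        else:
            i += 1
    return mentions


class CrfTagger:
    """Linear-chain CRF over BIO tags with hand-crafted lexical features.

    Parameters are an emission weight matrix (feature x label) and a label
    transition matrix (including a virtual start state).  Training
    minimizes the negative conditional log-likelihood plus an L2 penalty
    with L-BFGS; the optimization is deterministic, so equal corpora give
    byte-identical serialized models regardless of seed.
    """

    def __init__(self, l2: float = 0.1):
        self.l2 = l2
        self.labels: list[str] = []
        self.feature_index: dict[str, int] = {}
        self.emission: np.ndarray | None = None  # (n_features, n_labels)
        self.transition: np.ndarray | None = None  # (n_labels + 1, n_labels)

    # -- training ----------------------------------------------------------

    def fit(
        self,
        corpus: list[AnnotatedDocument],
        iterations: int = 343,
        seed: int = 0,
        schema: SchemaGraph | None = None,
    ) -> "CrfTagger":
        if not corpus:
            raise ValueError("training corpus is empty")
        if schema is not None:
            for doc in corpus:
                for mention in doc.gold:
                    if mention.label not in schema.classes:
                        raise ValueError(
                            f"gold label {mention.label!r} not present in schema"
                        )
        del seed  # training is deterministic; accepted for interface stability

        sequences = []
        label_set: set[str] = {"O"}
        for doc in corpus:
            tokens, labels = _bio_encode(doc)
            if tokens:
                sequences.append(([t.surface for t in tokens], labels))
                label_set.update(labels)
        self.labels = sorted(label_set)
        lab_idx = {lab: i for i, lab in enumerate(self.labels)}

        feat_seqs = []
        for words, labels in sequences:
            feats = [_token_features(words, i) for i in range(len(words))]
            for fs in feats:
                for f in fs:
                    self.feature_index.setdefault(f, len(self.feature_index))
            feat_seqs.append(
                (
                    [[self.feature_index[f] for f in fs] for fs in feats],
                    [lab_idx[lab] for lab in labels],
                )
            )

        n_feat, n_lab = len(self.feature_index), len(self.labels)
        n_em = n_feat * n_lab

        def unpack(theta):
            return (
                theta[:n_em].reshape(n_feat, n_lab),
                theta[n_em:].reshape(n_lab + 1, n_lab),
            )

        def neg_ll(theta):
            em, tr = unpack(theta)
            g_em = np.zeros_like(em)
            g_tr = np.zeros_like(tr)
            nll = 0.5 * self.l2 * float(theta @ theta)
            g = self.l2 * theta
            for feat_ids, y in feat_seqs:
                n = len(y)
                scores = np.zeros((n, n_lab))
                for i, ids in enumerate(feat_ids):
                    scores[i] = em[ids].sum(axis=0)
                # forward (log space)
                alpha = np.zeros((n, n_lab))
                alpha[0] = scores[0] + tr[n_lab]
                for i in range(1, n):
                    prev = alpha[i - 1][:, None] + tr[:n_lab]
                    m = prev.max(axis=0)
                    alpha[i] = scores[i] + m + np.log(
                        np.exp(prev - m).sum(axis=0)
                    )
                m = alpha[-1].max()
                log_z = m + np.log(np.exp(alpha[-1] - m).sum())
                # backward
                beta = np.zeros((n, n_lab))
                for i in range(n - 2, -1, -1):
                    nxt = beta[i + 1] + scores[i + 1] + tr[:n_lab]
                    m2 = nxt.max(axis=1)
                    beta[i] = m2 + np.log(np.exp(nxt - m2[:, None]).sum(axis=1))
                # gold score
                gold = scores[0, y[0]] + tr[n_lab, y[0]]
                for i in range(1, n):
                    gold += scores[i, y[i]] + tr[y[i - 1], y[i]]
                nll += log_z - gold
                # marginals
                post = alpha + beta
                post -= post.max(axis=1, keepdims=True)
                post = np.exp(post)
                post /= post.sum(axis=1, keepdims=True)
                for i, ids in enumerate(feat_ids):
                    g_em[ids] += post[i]
                    g_em[ids, y[i]] -= 1.0
                # transition marginals
                g_tr[n_lab] += post[0]
                g_tr[n_lab, y[0]] -= 1.0
                for i in range(1, n):
                    pair = (
                        alpha[i - 1][:, None]
                        + tr[:n_lab]
                        + scores[i][None, :]
                        + beta[i][None, :]
                    )
                    pair -= pair.max()
                    pair = np.exp(pair)
                    pair /= pair.sum()
                    g_tr[:n_lab] += pair
                    g_tr[y[i - 1], y[i]] -= 1.0
            g += np.concatenate([g_em.ravel(), g_tr.ravel()])
            return nll, g

        theta0 = np.zeros(n_em + (n_lab + 1) * n_lab)
        result = minimize(
            neg_ll,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": iterations, "maxfun": 10 * iterations},
        )
        self.emission, self.transition = unpack(result.x)
        return self

    # -- inference ---------------------------------------------------------

    def _transition_mask(self) -> np.ndarray:
        """BIO validity: I-X may only follow B-X or I-X."""
        n_lab = len(self.labels)
        mask = np.zeros((n_lab + 1, n_lab))
        for j, lab in enumerate(self.labels):
            if lab.startswith("I-"):
                cls = lab[2:]
                for i in range(n_lab + 1):
                    prev = self.labels[i] if i < n_lab else "<s>"
                    if prev not in ("B-" + cls, "I-" + cls):
                        mask[i, j] = -np.inf
        return mask

    def tag(self, doc: Document) -> list[EntityMention]:
        if self.emission is None:
            raise ValueError("model is not trained")
        tokens = tokenize(doc.text)
        if not tokens:
            return []
        words = [t.surface for t in tokens]
        n_lab = len(self.labels)
        scores = np.zeros((len(words), n_lab))
        for i in range(len(words)):
            for f in _token_features(words, i):
                idx = self.feature_index.get(f)
                if idx is not None:
                    scores[i] += self.emission[idx]
        mask = self._transition_mask()
        tr = self.transition + mask
        # Viterbi
        delta = scores[0] + tr[n_lab]
        back = np.zeros((len(words), n_lab), dtype=int)
        for i in range(1, len(words)):
            cand = delta[:, None] + tr[:n_lab]
            back[i] = cand.argmax(axis=0)
            delta = scores[i] + cand.max(axis=0)
        path = [int(delta.argmax())]
        for i in range(len(words) - 1, 0, -1):
            path.append(int(back[i, path[-1]]))
        path.reverse()
        labels = [self.labels[j] for j in path]
        return bio_to_mentions(doc.text, tokens, labels)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "crf",
                "l2": self.l2,
                "labels": self.labels,
                "features": sorted(
                    self.feature_index, key=self.feature_index.__getitem__
                ),
                "emission": self.emission.tolist(),
                "transition": self.transition.tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CrfTagger":
        data = json.loads(text)
        model = cls(l2=data["l2"])
        model.labels = data["labels"]
        model.feature_index = {f: i for i, f in enumerate(data["features"])}
        model.emission = np.asarray(data["emission"])
        model.transition = np.asarray(data["transition"])
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CrfTagger":
        return cls.from_json(Path(path).read_text())


def train_tagger(
    corpus: list[AnnotatedDocument],
    iterations: int = 343,
    seed: int = 0,
    schema: SchemaGraph | None = None,
    l2: float = 0.1,
) -> CrfTagger:
    """Train the CRF tagger; deterministic given corpus and seed."""
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    return CrfTagger(l2=l2).fit(corpus, iterations=iterations, seed=seed, schema=schema)


# ---------------------------------------------------------------------------
# Evaluation and corpus I/O


def span_f1(
    gold: list[EntityMention], predicted: list[EntityMention]
) -> tuple[float, float, float]:
    """Span-level (precision, recall, F1); a hit must match offsets and label."""
    gold_set = {(m.span.start, m.span.end, m.label) for m in gold}
    pred_set = {(m.span.start, m.span.end, m.label) for m in predicted}
    if not pred_set and not gold_set:
        return 1.0, 1.0, 1.0
    tp = len(gold_set & pred_set)
    precision = tp / len(pred_set) if pred_set else 0.0
    recall = tp / len(gold_set) if gold_set else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def write_conll(docs: list[AnnotatedDocument], path: str | Path) -> None:
    """Two-column (token <TAB> BIO-label) format, blank line between documents."""
    lines = []
    for doc in docs:
        tokens, labels = _bio_encode(doc)
        for t, lab in zip(tokens, labels):
            lines.append(f"{t.surface}\t{lab}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_conll(path: str | Path) -> list[AnnotatedDocument]:
    """Read two-column CoNLL text; document text is space-joined tokens."""
    docs: list[AnnotatedDocument] = []
    block: list[tuple[str, str]] = []

    def flush(n: int) -> None:
        if not block:
            return
        text = " ".join(tok for tok, _ in block)
        doc = Document(id=f"conll_{n:04d}", text=text)
        tokens = tokenize(text)
        labels = [lab for _, lab in block]
        docs.append(AnnotatedDocument(doc, bio_to_mentions(text, tokens, labels)))
        block.clear()

    for line in Path(path).read_text().splitlines():
        if not line.strip():
            flush(len(docs))
            continue
        tok, lab = line.split("\t")
        block.append((tok, lab))
    flush(len(docs))
    return docs
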