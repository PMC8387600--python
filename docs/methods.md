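# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic-data generators emulate,
and the design choices made where the design was genuinely open. It
states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Schemas

The BKG schema holds 124 entity classes and 46 typed relations. The
class inventory is a packaged list of 123 UMLS-semantic-type-style
names plus the custom `Data_Source` class that records the origin of
facts (the only class flagged `is_custom`). UMLS itself is
license-gated and its full release is not redistributable, so the
packaged list is a stand-in that honors the class count and naming
style; the schema loader accepts a YAML config for deployments that
carry their own inventory. Every relation declares explicit domain and
range class sets, and every endpoint must resolve — this is validated
on every build and parse.

The HIPAA ontology schema has a fixed structure: `Stakeholder` with
exactly three pairwise-disjoint subclasses (`Business_Associates`,
`Exempt_Entities`, `Covered_Entities`), `Regulation`, `CovidRule` with
the four COVID guidance subclasses (`Media_Access`,
`Contacting_Covid19_Patients`, `PHI_To_Law_Enforcement`, `Telehealth`),
and privacy/security rule classes carrying seven subclasses combined
(four privacy, three security — the split between the two was an open
choice; "seven combined" was adopted). Object properties
`hasRegulation`, `hasCovidRule`, `hasPrivacyRule`, `hasSecurityRule`
link the declared classes.

Both schema kinds serialize to Turtle and OWL/XML through rdflib and
round-trip losslessly. Disjointness is emitted as pairwise
`owl:disjointWith` axioms; the parser reassembles groups from connected
components, which is exact because the serializer always emits full
cliques.

## Entity tagging

Tokenization is regex-based: maximal alphanumeric runs keeping internal
hyphens and apostrophes (`COVID-19` is one token), all other non-space
characters as single tokens. Character offsets are 0-based, half-open.

Two taggers share one interface:

* **Gazetteer** — longest-match, leftmost-first dictionary tagging.
  Entries containing digits or hyphens match case-sensitively (so
  `COVID-19` does not match `covid-19`); all other entries match
  case-insensitively. A brute-force window-scan oracle in the test
  suite pins this behavior.
* **Linear-chain CRF** — BIO tags over token sequences, with lexical
  features (word identity, lowercase form, prefix/suffix, shape,
  hyphen/digit flags, adjacent words) and a full label-transition
  matrix including a virtual start state. Training minimizes the
  negative conditional log-likelihood with an L2 penalty
  (`l2 = 0.1`) by L-BFGS, default 343 iterations. The optimization
  starts from zero weights and uses no sampling, so training is
  deterministic and equal corpora yield byte-identical serialized
  models; the `seed` parameter is accepted for interface stability.
  Decoding is Viterbi with transitions into `I-X` masked off except
  from `B-X`/`I-X`, so emitted spans are always BIO-consistent.

The CRF is trained here only on synthetic corpora; reproducing any
externally published tagger's weights is out of scope.

## Relation extraction

Candidate generation is purely schema-driven: every ordered mention
pair whose (head label, tail label) is admitted by at least one
relation's domain/range survives, carrying its full admissible relation
set in schema declaration order. This matches a brute-force
enumeration oracle by construction and by test.

Pairs are embedded as the concatenation of the head and tail phrase
embeddings (`2d` dimensions; phrase embedding is the unweighted mean of
word vectors, out-of-vocabulary words contributing zero vectors). The
classifier is a feedforward network `[2d, 200, 100, 100, R+1]` with
ReLU hidden activations and a softmax output over the schema's `R`
relations plus an explicit no-relationship class (index `R`). For the
default schema and `d = 200` this is `[400, 200, 100, 100, 47]`.

At inference the schema constraint is applied a second time, at class
level: probabilities of relations not admissible for the pair are
masked to zero and the remaining mass renormalized
(`mask_renormalize=False` gives the filter-only alternative). The
argmax wins, ties broken by schema declaration order; a winning
relation below the confidence threshold (default 0.5) is demoted to
no-relationship.

Training is per-sample SGD on the unmasked cross-entropy, learning rate
0.01, 200 epochs by default, with seeded epoch reshuffling — fully
deterministic. Mean epoch losses are recorded and asserted
non-increasing within a tolerance of 1e-3.

## Knowledge graph and provenance

Entity IRIs are minted from normalized surface text (lowercase,
whitespace to underscores, residual characters percent-encoded) under
the single `BKG:` namespace; mentions with equal normalized surfaces
collapse onto one node. All facts are IRI-to-IRI triples; surfaces are
attached as `rdfs:label` and document identity as a `BKG:from_paper`
annotation. SPARQL runs through rdflib; result rows without an
explicit `ORDER BY` are sorted lexicographically for determinism.

The printed form of the worked data-source query is syntactically
garbled (its last triple pattern drops the object variable); the
packaged `WORKED_EXAMPLE_QUERY` is the obvious corrected pattern
`?x BKG:indicates ?y .` — a transcription fix, not a semantic change.

Provenance tracing is document-level: a fact's data source is the
`Data_Source`-typed entity sharing the fact's `from_paper` annotation.
When several sources share the document, one directly linked to the
fact's endpoints is preferred; a fact with no reachable source raises a
missing-provenance error.

## Policy analytics

* **Key terms** — bag-of-words counts after lowercasing, stopword
  removal (packaged ~130-word list, configurable) and removal of the
  modal verbs reserved for deontic detection; ties break
  alphabetically.
* **Deontic statements** — sentence segmentation splits on `[.?!]`
  followed by whitespace and a capital, guarded by an abbreviation
  list. One statement per sentence containing a modal; the first modal
  is the trigger and fixes the category. Default sets: permission
  `{will, can, could, may, might}`, obligation `{must, should, shall}`.
  "may" lives in the permission set — permission-style guidance
  sentences routinely open with it — even though it is simultaneously
  an inherently vague term; both sets are configurable and must be
  disjoint.
* **Semantic key-term frequency** — exact (case-insensitive) matches
  always count; with an embedding provider, tokens whose cosine
  similarity to any key term reaches the threshold (default 0.8) also
  count.
* **Document similarity** — `arccos` of the clamped cosine between
  document vectors, in radians in `[0, π]`; symmetric, 0 for identical
  documents. The packaged embedder is a deterministic hashing model:
  each word hashes (BLAKE2 of word and seed) to a unit Gaussian
  vector, the document vector is the token mean. It is a fixed,
  corpus-independent stand-in for trained paragraph-vector models: it
  gives exact determinism and platform independence but captures no
  distributional semantics, so absolute similarity values are not
  comparable to those of a trained embedder — the contract (radians,
  symmetry, bounds, vector-level recomputability) is what the tests
  pin.
* **Ambiguous-word ratio** — among alphabetic, non-stopword tokens
  found in the lexical database, the fraction with more than one
  sense. The database is pluggable (word → synset count, loadable from
  TSV); counting is per token, not per type. The packaged toy lexicon
  is synthetic and enumerable.
* **Vague-term ratio** — matches against a packaged four-category
  taxonomy (modal verbs; conditional; generalization; generalizing
  numeric terms, including multi-word phrases such as "as needed" and
  "including but not limited to"), longest match wins, matches never
  overlap; the denominator is the word-token count.
* **Reading complexity** — the Dale–Chall raw score
  `0.1579·(% difficult words) + 0.0496·(average sentence length)`,
  plus 3.6365 when difficult words exceed 5%. Difficult = non-numeric
  and absent from the familiar-word list. The packaged list is a
  compact (~650-word) common-word list; deployments wanting the full
  published familiar-word inventory can pass their own. As a vagueness
  component the raw score is divided by 10 to bring it onto the scale
  of the two ratio components; this normalization is a package
  interpretation (the published per-organization component values are
  far below raw Dale–Chall magnitudes and their normalization is
  unstated), and the raw score remains available.
* **Aggregate vagueness** — the plain sum of the three components;
  published component/total rows confirm the summation identity
  exactly, so rescaling onto (1, 3) is implemented only as an optional
  corpus-level affine post-step, off by default.

## Compliance and access control

Populating the HIPAA ontology types each organization under a
stakeholder subclass and creates one rule individual per deontic
statement, typed by a configurable keyword map (media → media access;
plasma/contact → contacting recovered patients; law/responder → PHI to
law enforcement; telehealth/remote → telehealth; unmatched statements
attach to the generic rule class). Coverage is asserted per subclass
by SPARQL over the populated graph and cross-checked against a direct
traversal oracle in the tests. The four report signals are presented
side by side; no composite compliance scalar is invented, since the
signals have incommensurable scales and directions (lower similarity
means closer to the regulation).

Access decisions compile a source's rules into attribute predicates by
restriction-keyword patterns — the packaged pattern covers the
no-commercial-use case, yielding a role predicate ("Is the user a
commercial agent?") and a purpose predicate ("Does the user intend to
share this information for commercial purposes?") — evaluated by
case-insensitive exact match against the request attributes. The
verdict is allow iff every predicate passes; the justification records
each question and answer, so replaying it reproduces the verdict.
Sources without a policy on record are denied (fail-closed), the
protective default. Predicate compilation is pattern-based, not
general language understanding.

## Synthetic data

The generators are pure functions of a `FixtureSpec` (all randomness
through `numpy.random.default_rng(seed)`, PCG64, the single RNG fixed
project-wide) and return exact ground truth alongside their output.

* The **policy corpus** generator emulates policy documents with
  controllable per-modal and per-vague-category densities and a
  key-term placement plan. Defaults: 10 documents of 12 sentences;
  modal densities 0.10–0.15 per modal; vague densities 0.10–0.15 over
  the three non-modal categories; 27 key-term insertions over three
  terms — enough planted events per class for count-recovery checks
  while keeping test runtime in seconds. Sentences draw fillers from a
  vocabulary verified disjoint from every modal, vague term and key
  term, and carry at most one modal each, so planted counts are exact
  by construction.
* The **annotated corpus** generator emulates paper passages: 3
  sentences per document, each planting two inventory entities at
  recorded offsets; candidate pairs are labelled from a relation plan
  valid under the bundled 5-class/4-relation mini-schema. Relation
  labels are a deterministic function of the surface pair, making the
  classification task separable by design.

These corpora are deliberately unlike real text: no syntax, no
discourse, no distributional structure, no ambiguity beyond what is
planted. Passing tests therefore demonstrate the correctness of the
mechanics (offset bookkeeping, schema constraints, count recovery,
learnability of separable signal) — not tagging or extraction quality
on real biomedical or legal prose, which depends on annotated corpora
and trained embeddings outside the package.

## Numerical choices and degenerate inputs

Softmax is computed with max-subtraction; cosine inputs to `arccos` are
clamped to [−1, 1]; a document embedding to the zero vector makes
similarity undefined and raises. Empty corpora, empty training sets,
degenerate rescaling ranges, overlapping modal sets, unknown labels and
unknown organizations all raise typed errors rather than propagating
silently. Ratio denominators of zero return 0 (ambiguity, vagueness) or
raise (readability, where an empty document has no defined score).

## Known limitations

* The packaged class inventory, familiar-word list and toy lexicon are
  stand-ins honoring published counts and contracts, not the
  license-gated originals.
* The hashing document embedder carries no semantics; similarity
  magnitudes are not comparable across embedders.
* Rule-to-category mapping and predicate compilation are keyword- and
  pattern-based and will miss paraphrases.
* No OWL reasoning or inference materialization; SPARQL answers are
  over asserted triples only. Inference-attack resistance is out of
  scope.
* Deontic detection is sentence-level and modal-triggered; dispensation
  and prohibition are not separated from the permission/obligation
  split, and negation ("may not") is not analyzed.
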