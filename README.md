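# covidkg

A framework for the secure extraction and governed sharing of COVID-19
knowledge from research-paper text. It is aimed at groups who mine the
pandemic literature into machine-readable form and must, at the same
time, respect the privacy rules that govern the underlying health data:
biomedical text-mining practitioners, health-data stewards, and
researchers studying policy compliance.

The package implements three connected stages:

1. **Biomedical knowledge graph (BKG).** Entity mentions are tagged
   against a 124-class schema of UMLS-semantic-type-style classes plus a
   custom `Data_Source` provenance class, either by a trainable
   linear-chain CRF or a deterministic gazetteer. Candidate entity pairs
   that the schema's 46 typed relations admit are classified by a
   four-layer feedforward network — input `2d = 400` for `d = 200`
   word-embedding dimensions, hidden layers 200/100/100, and a 47-way
   softmax (46 relations plus an explicit *no relationship* class).
   The extracted facts become an RDF graph, queryable with SPARQL, in
   which each fact can be traced back to the data source it came from.

2. **Policy compliance signals.** Privacy-policy text is scored against
   HIPAA COVID-19 guidance with four signals: coverage of the four
   COVID rule categories (media access, contacting recovered patients,
   PHI to law enforcement, telehealth) in a populated HIPAA ontology;
   the frequency of regulation key terms and semantically similar
   tokens; the angular distance `arccos(cos(v_policy, v_regulation))`
   between document vectors (radians — lower is closer to the
   regulation); and a vagueness score

   `V = A + G + C`

   where `A` is the fraction of content words with more than one sense
   in a lexical database, `G` the fraction of word tokens matching a
   four-category taxonomy of inherently vague terms, and `C` a
   normalized Dale–Chall reading-complexity component
   (`raw = 0.1579·pct_difficult + 0.0496·avg_sentence_len`, plus 3.6365
   when difficult words exceed 5%).

3. **Access control.** A request for a knowledge-graph fact is traced to
   its data source; the source's policy rules (sentences carrying modal
   verbs, categorized as permissions or obligations) compile into
   attribute predicates which are evaluated against the requesting
   user's attributes. Access is allowed only when every predicate
   passes; sources with no policy on record are denied by default.

## Worked example

```python
from covidkg import query, vagueness_score
from covidkg.fixtures import WORKED_EXAMPLE_QUERY, worked_example_graph

kg = worked_example_graph()
for x, y in query(kg, WORKED_EXAMPLE_QUERY):
    print(kg.label_of(x), "indicates", kg.label_of(y))

rows = query(kg, "SELECT ?y WHERE { BKG:covid-19 BKG:treats ?y . }")
print(sorted(kg.label_of(r[0]) for r in rows))

print(vagueness_score(0.657, 0.167, 0.98))
```

prints

```
anecdotal report indicates famotidine treatment
['famotidine', 'hydroxychloroquine', 'remdesevir']
1.804
```

The first two lines answer SPARQL queries on the packaged single-paper
example graph: the data source *anecdotal report* indicates the
therapeutic procedure *famotidine treatment*, and COVID-19 is linked by
`treats` to three drug entities. The last line aggregates a policy's
three vagueness components into its total score.

The same functionality is available from the shell:

```sh
covidkg schema build --kind bkg --out schema.ttl
covidkg graph example --out graph.ttl
covidkg policy dls my_policy.txt
covidkg comply --org my_policy.txt --hipaa hipaa_guidance.txt
covidkg access --request request.json --policy-dir policies/
```

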