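# acukg

Construction pipeline for a knowledge graph of **acupuncture and tuina**
(Chinese therapeutic massage) from Chinese-language text, aimed at TCM
informatics work: organizing diseases, symptoms, acupoints, therapies and
their effects into a queryable graph that can back retrieval and
treatment-recommendation tools.

The schema has five entity types — disease (`DIS`), symptom (`SYM`),
acupoint/meridian (`XW`), therapy (`OPE`), function (`FUN`) — and six typed
relations (`DIS-SYM`, `DIS-OPE`, `DIS-XW`, `OPE-XW`, `OPE-FUN`, `XW-FUN`).
The pipeline is hybrid:

* **Dictionary NER** — one trie per entity type; greedy longest-match
  scanning emits non-overlapping spans of at most 10 characters.
* **TemplateFC model NER** — template-free prompt tuning for few-shot
  Chinese NER.  Tagging is recast as language modeling with a label-word
  map `M: Y → V_l`: the LM learns to predict `M(y_i)` at entity positions
  and the original character elsewhere,

      L_word = − Σ_i log P(x_i = x_i^Ent | X),

  and is trained jointly with a BiLSTM-CRF over the encoder embeddings,

      L_entity = − log ( e^{S_gold} / Σ_paths e^{S_path} ),
      L_all    = L_word + L_entity,

  where a path's score S is the sum of emission and transition scores.
  Decoding is per-position argmax through `M⁻¹` or Viterbi through the CRF.
* **Fusion** — per-position merge of dictionary and model tags (model fills
  dictionary gaps, dictionary wins logged conflicts) plus BIO repair.
* **Rule-based relation extraction** — subject-word rules driven by the
  title's entity, a therapy–acupoint proximity rule, and efficacy-keyword
  rules (功效/作用/功能).
* **Graph assembly** — networkx multigraph with an isolated-node filter
  (dictionary entities enter only if the corpus mentions them), one-hop
  queries, stats, and Cypher/GraphML/CSV export.

A seeded synthetic fixture generator produces dictionaries, templated
corpora with exact gold BIO labels and gold relation triples, so every
stage is testable end to end without external data.

## Worked example

```python
from acukg import FixtureSpec, generate_fixture, run_pipeline

dictionary, docs, ledger = generate_fixture(FixtureSpec(n_documents=12, seed=0))
result = run_pipeline(docs, dictionary)
print(result.graph.stats())
subject = ledger.title_spans[docs[0].doc_id][0].surface
print(result.graph.one_hop(subject))
```

prints

```
{'entity_counts': {'DIS': 7, 'SYM': 7, 'XW': 8, 'OPE': 6, 'FUN': 6},
 'entity_total': 34,
 'relation_counts': {'DIS-SYM': 12, 'DIS-OPE': 9, 'DIS-XW': 10,
                     'OPE-XW': 18, 'OPE-FUN': 11, 'XW-FUN': 11},
 'relation_total': 71, 'dropped_triples': 0}
{'found': True, 'entity': '唿唶唷啝', 'etype': 'DIS',
 'relations': {'DIS-OPE': ['噚噿', '噪噸嚈噔'],
               'DIS-SYM': ['啫嗁喙喇喧', '喎喔喫', '喨嗃喥', '嗇喴嗆'],
               'DIS-XW': ['嗢嗞嘏嘆嗌', '嗭嘛', '嘫嗛嘦']}}
```

The 12 synthetic documents yield a graph of 34 entities and 71 relations;
the one-hop query on the first document's subject disease returns its
symptoms, recommended therapies and treatment acupoints grouped by relation
type — the question-answering pattern the graph exists to serve.

Few-shot NER:

```python
from acukg import TemplateFCTagger, entity_f1
from acukg.synthetic import few_shot_episode_per_type

train, test = few_shot_episode_per_type(ledger, per_type=10, seed=0)
model = TemplateFCTagger(seed=0).fit([s for s, _ in train], [t for _, t in train])
print(entity_f1(test, model.predict([s for s, _ in test])))
```

`TemplateFCTagger` is a scikit-learn style estimator (`fit` / `predict` /
`get_params`); `TrieTagger` wraps the dictionary matcher in the same
interface.

There is also a CLI (`acukg make-fixtures / annotate / train / predict /
build-kg / query / export`); run `acukg --help`.

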