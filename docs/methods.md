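# Methods

## Problem and pipeline

The package builds a typed knowledge graph of acupuncture and tuina
(Chinese therapeutic massage) knowledge from Chinese-language text.  The
schema has five entity types — disease (DIS), symptom (SYM),
acupoint/meridian (XW), therapy (OPE), function/effect (FUN) — and six
relation types with fixed type signatures (DIS-SYM, DIS-OPE, DIS-XW,
OPE-XW, OPE-FUN, XW-FUN).  Construction proceeds in five stages:

1. **Dictionary NER** — one prefix tree (trie) per entity type built from a
   curated surface-form dictionary (entity length capped at 10 characters);
   greedy longest-match scanning of each sentence, left to right.
2. **Model NER** — the TemplateFC model (below), trained on the dictionary
   annotations (or any BIO corpus), re-tags the text to surface entities
   the dictionary missed.
3. **Fusion** — per-position merging of the two tag sequences followed by
   BIO repair.
4. **Relation extraction** — three rule families (subject-word, proximity,
   efficacy-keyword) emit typed triples with provenance.
5. **Graph assembly** — entities and triples become a networkx multigraph
   with the isolated-node filter; one-hop query, statistics, and export to
   Cypher / GraphML / CSV.

Tokenization is character-level throughout.  This is the natural unit for
Chinese, avoids a word-segmenter dependency, and matches the observation
that domain entities span many characters (so any word-level unit would
have to be split again anyway).

## Schema decisions

* **Disease vs symptom.**  Ordinary clinical language does not separate the
  two ("headache" is both).  The scope rule is: a candidate surface is DIS
  iff it appears (exact match after whitespace normalization) in a
  user-supplied disease nomenclature list (ICD-10 and/or GB/T 16751.1 term
  lists, one term per line; the standards themselves are licensed and not
  redistributed here), otherwise SYM.
* **Meridians are acupoint attributes**, not nodes: acupoints lie on
  meridians and the meridian inventory is tiny, so meridian is stored as a
  node attribute of type-XW entities, along with the operation method.
* **Structured records.**  A disease record contributes one DIS-SYM triple
  per listed symptom (deduplicated, provenance `structured_kb`); hospital
  section and disease site are node attributes only, since no schema
  relation covers them.  An acupoint record contributes XW-FUN triples, one
  per function phrase.  Function fields mix functions with indications
  ("Invigorate the meridians: Migraine"); phrases are split at (Chinese)
  semicolons and truncated at a colon, keeping only the function part,
  because the schema has no acupoint-disease relation.

## Trie extraction

Insertion marks only the final node of a word's path as end-of-word.
Scanning tries candidate lengths from 10 down to 1 at each position and,
on the first (longest) match, emits the span and resumes *after* it; this
makes matches non-overlapping and suppresses entities nested inside an
accepted longer entity ("神经官能症" inside "胃肠神经官能症"), which is the
behaviour the method needs for Chinese text.  The five per-type tries run
independently; overlapping candidates of different types are arbitrated by
span length first, then a fixed type priority DIS > SYM > XW > OPE > FUN
(corpus frequency order).  The brute-force oracle used in testing scans all
≤10-character substrings against a plain set with the same greedy policy.

## The TemplateFC model

Few-shot NER is recast as language modeling (an entity-oriented LM
objective): a mapping M from each B-/I- tag to a *label word* in the
vocabulary turns a tagged sentence (X, Y) into a target sequence X_Ent that
equals X except at entity positions, where it carries M(y_i).  No
natural-language template is constructed — important for Chinese, where
template search spaces are large and entities span many tokens.  The LM
loss is

    L_word = − Σ_i log P(x_i = x_i^Ent | X).

Per-position LM prediction has no notion of tag continuity, so a BiLSTM
reads the encoder's embedding vectors W and produces an n×l emission
matrix, scored by a linear-chain CRF: a path's score is the sum of
emission, transition and boundary scores, and

    L_entity = − log ( e^{S_gold} / Σ_paths e^{S_path} ),

the negative log of the gold path's probability, with the partition
computed by the forward algorithm in log space.  The joint objective is
L_all = L_word + L_entity (weights configurable).  Decoding is either
per-position argmax mapped back through M (token = x_i → O, token = M(y) →
y, otherwise O), or Viterbi through the CRF; both are followed by BIO
repair.  Argmax suits data-rich settings; Viterbi (the default) is the
right choice in few-shot settings where per-position predictions are
noisier.

**Label-word selection** combines a data search and an LM search: for each
tag, every vocabulary word w is scored by

    count(w at positions tagged y) × mean P(w | X) over those positions,

words ranking in more than one tag's top list are discarded as ambiguous,
and the top-k survivors (k = 1 by default; selections are distinct across
tags) become the tag's label words.  The exact combination rule is a
package choice; the multiplicative form rewards words that are both
frequent under the tag and natural to the LM at those positions.  A tag
with zero corpus occurrences is a hard error naming the tag.

**Encoder.**  The encoder contract is: character-id sequence → per-position
embedding vectors W plus per-position vocabulary distributions.  The
default is a small trainable character-embedding + BiLSTM + projection LM
head (embedding 32, encoder hidden 32/direction), which keeps the whole
model trainable on one CPU in seconds per epoch; any pretrained Chinese
masked LM exposing the same contract can be dropped in.

**CRF constraints.**  Transitions producing an orphan I-tag (O→I-t,
B-s→I-t and I-s→I-t for s≠t, and sequence-initial I-t) carry an additive
penalty of −1e4, toggleable.  This makes BIO validity structural rather
than learned.

**Training.**  Adam, learning rate 5e-3, 60 epochs, batch size 8, all
config-driven.  The schedule was chosen so the joint loss of the tiny
encoder reliably converges on few-shot corpora of a few dozen sentences;
a pretrained encoder would want a far smaller rate (~1e-5).  Two dropout
mechanisms regularize training: standard dropout (0.1) on W before the
emission BiLSTM, and *unk-dropout* (0.2), which replaces input characters
with `<unk>` while keeping the original LM target.  Unk-dropout is what
makes the few-shot model generalize to entities whose characters never
occur in the training sentences: it forces the model to type entities from
their context rather than memorizing characters.  Training is deterministic
given the seed (initialization, shuffling and both dropouts all draw from
one seeded generator); a non-finite loss aborts with diagnostics rather
than training through NaNs.

## Fusion

Per position: equal tags stand; a model entity tag overrides a dictionary
O (the model's job is to find what the dictionary missed); a dictionary
entity tag overrides a model O (curated knowledge is not discarded); two
different non-O tags are a logged conflict resolved in favour of the
dictionary, on the grounds that the dictionary is curated while the model's
type call on a contested span is the weaker signal.  A fused tag is O only
when both inputs are O.  BIO repair (orphan I-t → B-t) runs afterwards, so
fusion output is always a valid tagging.

## Relation rules

* **Subject rule.**  The title names the document's subject: a title
  containing a DIS entity marks disease-therapy literature (body SYM/OPE/XW
  entities attach to the subject as DIS-SYM/DIS-OPE/DIS-XW); a title with
  an OPE entity and no DIS marks therapy-introduction literature (body
  XW/FUN attach as OPE-XW/OPE-FUN, and a body DIS yields DIS-OPE with the
  subject as the therapy endpoint — the disease endpoint has to come from
  the body, since the subject itself is a therapy).  A title with several
  candidate subjects uses the first; disease outranks therapy.
* **Proximity rule.**  OPE and XW entities co-occurring in one sentence
  (default) or within a configurable character window yield OPE-XW.
* **Keyword rule.**  In sentences containing an efficacy keyword (功效 /
  作用 / 功能, configurable), every (OPE, FUN) pair yields OPE-FUN and
  every (XW, FUN) pair yields XW-FUN.

Duplicates across rules merge to one edge; the first firing's provenance
(doc id, sentence index, rule name) is kept.  All emitted triples are
signature-checked at construction.

## Graph assembly

Node identity is the NFC-normalized, trimmed surface form; no alias
merging (aliases, if supplied, are node attributes).  The isolated-node
filter admits a dictionary entity only if it occurs at least once in the
corpus; entities found by the model or ingested from structured records are
always admitted.  Triples with a filtered endpoint are dropped and counted,
never used to resurrect a node.  Self-loops are rejected.  One-hop queries
group both outgoing and incoming neighbors by relation type in sorted
order.  CSV export (nodes.csv + edges.csv) round-trips losslessly; Cypher
export emits one MERGE per node and per edge.

## Synthetic fixtures

The generator emulates short treatment prose: dictionary entities embedded
in recurring sentence patterns with punctuation-delimited sentences, e.g.
`<DIS>的症状包括<SYM>、<SYM>。` (disease-therapy class) and
`<OPE>操作：<XW>、<XW>。` (therapy-intro class).  The templates jointly
cover all six relation types and all three rule families.  Defaults: 8
entities per type, lengths 2–5 characters, 12 documents, no noise.

Entity surfaces are drawn from a fixed 500-character CJK inventory
partitioned into one disjoint 100-character slice per entity type, with the
template scaffold characters disjoint from all slices.  The partition gives
two guarantees: (a) *exactness* — no dictionary word can straddle an entity
boundary or match across types, so trie output provably equals the ledger
tags at zero noise and the end-to-end graph equals the gold graph; and (b)
*learnability* — with ten-odd training sentences per type, the few-shot
recovery experiment is well-posed rather than hopeless.  Optional
distractor noise inserts characters from a separate alphabet at sentence
starts only, shifting but never corrupting planted spans.

What the fixtures do **not** emulate: real prose style, cross-type
character sharing, genuinely ambiguous surfaces, segmentation errors, OCR
noise, or headings/sections.  Passing tests on fixtures therefore
demonstrate algorithmic correctness (the stages compute what they are
defined to compute) and few-shot learnability under clean conditions — not
performance on real clinical text, where dictionaries are imperfect and
context is far less regular.

## Verification set-up and problem sizes

* CRF forward/Viterbi vs exhaustive enumeration over all l^n paths:
  200 random instances, n ≤ 6, l ≤ 5, tolerance 1e-6.
* Trie extraction vs brute-force greedy substring matching: 200 random
  (dictionary, sentence) pairs, sentences up to 80 characters.
* Fusion: all 11×11 tag pairs against an independent restatement of the
  rule table.
* End-to-end: 12-document fixture at zero noise, exact node/edge equality
  with the gold ledger.
* Few-shot: 40-document fixture, at least 10 training sentences per entity
  type (~30 sentences), ~90 held-out sentences, three seeds; entity-level
  micro-F1 (exact span + type match) ≥ 0.9 per seed, and the per-epoch
  joint loss non-increasing across every 10-epoch window.

The published full-scale corpus statistics kept in `acukg.refstats`
(per-type entity and relation counts with their totals) are reference data
for arithmetic consistency checks; this package does not attempt to
reproduce them, since the underlying corpus is not redistributable.

## Known limitations

* Rule-based relation extraction cannot capture relations expressed across
  sentences or with anaphora; the subject rule trusts titles.
* The fusion conflict policy always prefers the dictionary; a weighted or
  probabilistic fusion is out of scope.
* The tiny encoder has no pretraining; on real text it would need far more
  than ten sentences per type, or a pretrained encoder behind the same
  contract.
* The trie is exact-match only; no fuzzy or pinyin-variant matching.
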