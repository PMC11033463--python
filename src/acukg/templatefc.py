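"""Template-free prompt-tuning NER with joint LM + BiLSTM-CRF training.

The model recasts character-level NER as language modeling: for an input
sentence ``X = x_1..x_n`` with BIO tags ``Y = y_1..y_n``, a mapping
``M: Y -> V_l`` assigns each entity tag a *label word* from the vocabulary,
and the LM is trained to emit the target sequence ``X_Ent`` that equals X
except at entity positions, where it carries ``M(y_i)``.  No natural-language
template is ever constructed, which matters for Chinese text where the
template search space is huge and entities span many characters.

Two losses are trained jointly (unit weights by default):

* ``L_word``  — the entity-oriented LM cross-entropy ``-sum_i log P(x_i = x_i_Ent | X)``;
* ``L_entity`` — a linear-chain CRF negative log-likelihood over emission
  scores produced by a BiLSTM reading the encoder's embeddings, which gives
  the model an explicit notion of tag continuity that pure per-position LM
  prediction lacks.

Decoding is either per-position argmax through the inverse label-word map
(cheap; suited to data-rich settings) or Viterbi through the CRF layer
(suited to few-shot settings).  Both are followed by BIO repair.

Label words are chosen by a combined data + LM search: each vocabulary word
is scored per tag by (its frequency at positions carrying the tag) times
(the mean probability the LM assigns it at those positions); words ranking
highly for more than one tag are discarded as ambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .autodiff import Adam, Tensor
from .bio import O_TAG, TAGS, bio_repair, validate_tag
from .crf import bio_transition_mask, crf_loss_t, viterbi

UNK = "<unk>"


class MissingTagError(ValueError):
    """Raised when label-word selection finds tags with zero corpus occurrences."""

    def __init__(self, tags: Sequence[str]):
        self.tags = list(tags)
        super().__init__(f"no corpus occurrences for tags: {', '.join(self.tags)}")


@dataclass
class LabelWordMap:
    """Mapping M from BIO tags to label words; O maps to the identity word.

    ``words[tag]`` holds the tag's k label words (vocabulary strings); they
    are distinct across tags.
    """

    words: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        flat = [w for ws in self.words.values() for w in ws]
        if len(flat) != len(set(flat)):
            raise ValueError("label words must be distinct across tags")

    def primary(self, tag: str) -> str:
        return self.words[tag][0]

    def inverse(self) -> dict[str, str]:
        return {w: tag for tag, ws in self.words.items() for w in ws}

    def to_json(self) -> str:
        return json.dumps(self.words, ensure_ascii=False)

    @classmethod
    def from_json(cls, s: str) -> "LabelWordMap":
        return cls(json.loads(s))


class TinyEncoder(nn.Module):
    """Character-embedding + BiLSTM encoder with an LM projection head.

    Satisfies the encoder contract: given a character-id sequence it returns
    per-position embedding vectors ``W`` and per-position log-probabilities
    over the vocabulary.  A pretrained masked LM exposing the same contract
    can be substituted.
    """

    def __init__(self, vocab_size: int, embed_dim: int, hidden: int, rng: np.random.Generator):
        self.embed = nn.Embedding(vocab_size, embed_dim, rng)
        self.bilstm = nn.BiLSTM(embed_dim, hidden, rng)
        self.lm_head = nn.Linear(2 * hidden, vocab_size, rng)

    def __call__(self, ids: Sequence[int]) -> tuple[Tensor, Tensor]:
        w = self.bilstm(self.embed(list(ids)))
        log_probs = self.lm_head(w).log_softmax(axis=1)
        return w, log_probs


def build_target_ids(
    x_ids: Sequence[int], tags: Sequence[str], label_map: LabelWordMap, vocab: dict[str, int]
) -> list[int]:
    """Target sequence X_Ent: label-word ids at entity positions, x_i elsewhere."""
    if len(x_ids) != len(tags):
        raise ValueError("ids and tags must have equal length")
    out = []
    for xid, tag in zip(x_ids, tags):
        validate_tag(tag)
        if tag == O_TAG:
            out.append(int(xid))
        else:
            out.append(vocab[label_map.primary(tag)])
    return out


def entlm_loss_t(log_probs: Tensor, target_ids: Sequence[int]) -> Tensor:
    """-sum_i log P(x_i = target_i | X) from per-position log-probabilities."""
    n = log_probs.shape[0]
    if len(target_ids) != n:
        raise ValueError("target length mismatch")
    picked = log_probs[np.arange(n), np.asarray(target_ids, dtype=np.int64)]
    return -picked.sum()


def entlm_loss(
    x_ids: Sequence[int],
    tags: Sequence[str],
    label_map: LabelWordMap,
    vocab: dict[str, int],
    encoder: Callable[[Sequence[int]], tuple[Tensor, Tensor]],
) -> float:
    """Entity-oriented LM loss of one sentence under an encoder."""
    _, log_probs = encoder(list(x_ids))
    targets = build_target_ids(x_ids, tags, label_map, vocab)
    return entlm_loss_t(log_probs, targets).item()


def select_label_words(
    corpus: Sequence[tuple[Sequence[int], Sequence[str]]],
    encoder: Callable[[Sequence[int]], tuple[Tensor, Tensor]],
    vocab: dict[str, int],
    k: int = 1,
    tags: Sequence[str] | None = None,
    top_list_size: int = 5,
) -> LabelWordMap:
    """Combined data + LM search for label words.

    For every tag, each vocabulary word is scored by
    ``count(word at tag positions) * mean P(word | X)`` over those positions.
    Words appearing in the top list of more than one tag are removed as
    ambiguous; the top-k survivors (distinct across tags, assigned in fixed
    tag order) become the tag's label words.
    """
    id_to_word = {i: w for w, i in vocab.items()}
    V = len(vocab)
    want = [t for t in (tags if tags is not None else TAGS) if t != O_TAG]

    counts = {t: np.zeros(V) for t in want}
    prob_sums = {t: np.zeros(V) for t in want}
    occur = {t: 0 for t in want}
    for x_ids, y_tags in corpus:
        x_ids = list(x_ids)
        _, log_probs = encoder(x_ids)
        probs = np.exp(log_probs.data)
        for i, tag in enumerate(y_tags):
            if tag in counts:
                counts[tag][x_ids[i]] += 1.0
                prob_sums[tag] += probs[i]
                occur[tag] += 1

    missing = [t for t in want if occur[t] == 0]
    if missing:
        raise MissingTagError(missing)

    scores = {}
    rankings = {}
    for t in want:
        mean_prob = prob_sums[t] / occur[t]
        scores[t] = counts[t] * mean_prob
        rankings[t] = np.argsort(-scores[t], kind="stable")  # ties -> lowest id

    top_lists = {
        t: {
            int(w)
            for w in rankings[t][: max(top_list_size, k)]
            if scores[t][int(w)] > 0
        }
        for t in want
    }
    conflict: set[int] = set()
    for t in want:
        for u in want:
            if u != t:
                conflict |= top_lists[t] & top_lists[u]

    words: dict[str, list[str]] = {}
    taken: set[int] = set()
    for t in want:
        chosen: list[str] = []
        for wid in rankings[t]:
            wid = int(wid)
            if len(chosen) == k:
                break
            if wid in conflict or wid in taken:
                continue
            chosen.append(id_to_word[wid])
            taken.add(wid)
        if len(chosen) < k:
            raise ValueError(f"cannot find {k} unambiguous label words for tag {t}")
        words[t] = chosen
    return LabelWordMap(words)


def decode_argmax(
    x_ids: Sequence[int],
    log_probs: np.ndarray,
    label_map: LabelWordMap,
    vocab: dict[str, int],
) -> list[str]:
    """Per-position argmax decoding through the inverse label-word map.

    The predicted token maps back to a tag: the original character means O,
    a label word means its tag, anything else falls back to O.  Followed by
    BIO repair.
    """
    inv = {vocab[w]: tag for w, tag in label_map.inverse().items()}
    tags = []
    for i, xid in enumerate(x_ids):
        pred = int(np.argmax(log_probs[i]))
        if pred == int(xid):
            tags.append(O_TAG)
        else:
            tags.append(inv.get(pred, O_TAG))
    return bio_repair(tags)


class TemplateFCTagger(BaseEstimator):
    """Few-shot character-level NER estimator with joint EntLM + BiLSTM-CRF training.

    Parameters
    ----------
    embed_dim, enc_hidden : int
        Character embedding size and encoder BiLSTM hidden size per direction.
    lstm_hidden : int
        Emission BiLSTM hidden size per direction.
    dropout : float
        Dropout rate on encoder outputs before the emission BiLSTM (training only).
    unk_dropout : float
        Probability of replacing an input character with ``<unk>`` during
        training (the LM target stays the original character).  Forces the
        model to type entities from their context, which is what carries a
        few-shot model onto entities it never saw in training.
    k : int
        Label words per tag.
    lm_weight, crf_weight : float
        Weights of the LM and CRF losses in the joint objective.
    epochs, batch_size, lr : training schedule (Adam).
    decode : {"viterbi", "argmax"}
        Viterbi suits few-shot settings; argmax suits data-rich ones.
    constrain_transitions : bool
        Mask BIO-invalid transitions with ``mask_penalty``.
    seed : int
        Controls initialization, shuffling and dropout; same seed, same model.

    Attributes
    ----------
    vocab_ : dict[str, int]
    label_word_map_ : LabelWordMap
    loss_trace_ : list[float]       mean per-sentence joint loss per epoch
    """

    def __init__(
        self,
        embed_dim: int = 32,
        enc_hidden: int = 32,
        lstm_hidden: int = 128,
        dropout: float = 0.1,
        unk_dropout: float = 0.2,
        k: int = 1,
        lm_weight: float = 1.0,
        crf_weight: float = 1.0,
        epochs: int = 60,
        batch_size: int = 8,
        lr: float = 5e-3,
        decode: str = "viterbi",
        constrain_transitions: bool = True,
        mask_penalty: float = -1e4,
        seed: int = 0,
    ):
        self.embed_dim = embed_dim
        self.enc_hidden = enc_hidden
        self.lstm_hidden = lstm_hidden
        self.dropout = dropout
        self.unk_dropout = unk_dropout
        self.k = k
        self.lm_weight = lm_weight
        self.crf_weight = crf_weight
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.decode = decode
        self.constrain_transitions = constrain_transitions
        self.mask_penalty = mask_penalty
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _encode_ids(self, sentence: str) -> list[int]:
        unk = self.vocab_[UNK]
        return [self.vocab_.get(ch, unk) for ch in sentence]

    def _emissions(self, w: Tensor, rng: np.random.Generator | None) -> Tensor:
        if rng is not None and self.dropout > 0:
            keep = (rng.random(w.shape) >= self.dropout) / (1.0 - self.dropout)
            w = w * Tensor(keep)
        return self.emission_head_(self.emission_bilstm_(w))

    def _masked_crf_params(self) -> tuple[Tensor, Tensor, Tensor]:
        trans = self.transitions_
        start = self.start_scores_
        end = self.end_scores_
        if self.constrain_transitions:
            tmask, smask, emask = bio_transition_mask(TAGS, self.mask_penalty)
            trans = trans + Tensor(tmask)
            start = start + Tensor(smask)
            end = end + Tensor(emask)
        return trans, start, end

    def _sentence_loss(
        self, x_ids: list[int], tags: list[str], rng: np.random.Generator | None
    ) -> Tensor:
        in_ids = x_ids
        if rng is not None and self.unk_dropout > 0:
            unk = self.vocab_[UNK]
            keep = rng.random(len(x_ids)) >= self.unk_dropout
            in_ids = [xid if k else unk for xid, k in zip(x_ids, keep)]
        w, log_probs = self.encoder_(in_ids)
        targets = build_target_ids(x_ids, tags, self.label_word_map_, self.vocab_)
        l_word = entlm_loss_t(log_probs, targets)
        emissions = self._emissions(w, rng)
        trans, start, end = self._masked_crf_params()
        path = [self.tag_index_[t] for t in tags]
        l_entity = crf_loss_t(emissions, trans, path, start, end)
        return self.lm_weight * l_word + self.crf_weight * l_entity

    def joint_loss(self, sentence: str, tags: Sequence[str]) -> dict[str, float]:
        """Joint objective of one sentence without dropout: components and total.

        Returns ``{"lm": L_word, "crf": L_entity, "total": lm_weight*L_word +
        crf_weight*L_entity}``.
        """
        if not hasattr(self, "encoder_"):
            raise RuntimeError("TemplateFCTagger is not fitted")
        x_ids = self._encode_ids(sentence)
        w, log_probs = self.encoder_(x_ids)
        targets = build_target_ids(x_ids, list(tags), self.label_word_map_, self.vocab_)
        l_word = entlm_loss_t(log_probs, targets).item()
        emissions = self._emissions(w, rng=None)
        trans, start, end = self._masked_crf_params()
        path = [self.tag_index_[t] for t in tags]
        l_entity = crf_loss_t(emissions, trans, path, start, end).item()
        return {
            "lm": l_word,
            "crf": l_entity,
            "total": self.lm_weight * l_word + self.crf_weight * l_entity,
        }

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: Sequence[str], y: Sequence[Sequence[str]]):
        """Train on sentences ``X`` with per-character BIO tag sequences ``y``."""
        if len(X) == 0:
            raise ValueError("cannot train on an empty corpus")
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        for sent, tags in zip(X, y):
            if len(sent) != len(tags):
                raise ValueError("each tag sequence must match its sentence length")

        rng = np.random.default_rng(self.seed)
        chars = sorted({ch for sent in X for ch in sent})
        self.vocab_ = {UNK: 0, **{ch: i + 1 for i, ch in enumerate(chars)}}
        self.tag_index_ = {t: i for i, t in enumerate(TAGS)}

        self.encoder_ = TinyEncoder(len(self.vocab_), self.embed_dim, self.enc_hidden, rng)
        self.emission_bilstm_ = nn.BiLSTM(2 * self.enc_hidden, self.lstm_hidden, rng)
        self.emission_head_ = nn.Linear(2 * self.lstm_hidden, len(TAGS), rng)
        self.transitions_ = Tensor(rng.uniform(-0.1, 0.1, (len(TAGS), len(TAGS))), requires_grad=True)
        self.start_scores_ = Tensor(rng.uniform(-0.1, 0.1, len(TAGS)), requires_grad=True)
        self.end_scores_ = Tensor(rng.uniform(-0.1, 0.1, len(TAGS)), requires_grad=True)

        corpus = [(self._encode_ids(s), list(t)) for s, t in zip(X, y)]
        observed = sorted(
            {tag for _, tags in corpus for tag in tags if tag != O_TAG},
            key=lambda t: self.tag_index_[t],
        )
        self.label_word_map_ = select_label_words(
            corpus, self.encoder_, self.vocab_, k=self.k, tags=observed
        )

        params = (
            self.encoder_.parameters()
            + self.emission_bilstm_.parameters()
            + self.emission_head_.parameters()
            + [self.transitions_, self.start_scores_, self.end_scores_]
        )
        opt = Adam(params, lr=self.lr)
        self.loss_trace_ = []
        order = np.arange(len(corpus))
        for epoch in range(self.epochs):
            rng.shuffle(order)
            total = 0.0
            for lo in range(0, len(order), self.batch_size):
                batch = order[lo : lo + self.batch_size]
                opt.zero_grad()
                losses = [self._sentence_loss(*corpus[i], rng) for i in batch]
                batch_loss = losses[0]
                for l in losses[1:]:
                    batch_loss = batch_loss + l
                batch_loss = batch_loss * (1.0 / len(batch))
                if not np.isfinite(batch_loss.item()):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {batch_loss.item()!r}; "
                        "try a lower learning rate"
                    )
                batch_loss.backward()
                opt.step()
                total += batch_loss.item() * len(batch)
            self.loss_trace_.append(total / len(corpus))
        return self

    def predict(self, X: Sequence[str]) -> list[list[str]]:
        """BIO tag sequences, decoded per the ``decode`` setting + BIO repair."""
        if not hasattr(self, "encoder_"):
            raise RuntimeError("TemplateFCTagger is not fitted")
        out = []
        for sent in X:
            if len(sent) == 0:
                out.append([])
                continue
            x_ids = self._encode_ids(sent)
            w, log_probs = self.encoder_(x_ids)
            if self.decode == "argmax":
                out.append(decode_argmax(x_ids, log_probs.data, self.label_word_map_, self.vocab_))
            elif self.decode in ("viterbi", "crf"):
                emissions = self._emissions(w, rng=None)
                trans, start, end = self._masked_crf_params()
                path = viterbi(emissions.data, trans.data, start.data, end.data)
                out.append(bio_repair([TAGS[i] for i in path]))
            else:
                raise ValueError(f"unknown decode mode {self.decode!r}")
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize weights (.npz) with a JSON sidecar (config + label words + vocab)."""
        path = Path(path)
        state = {
            "encoder": self.encoder_.state_dict(),
            "emission_bilstm": self.emission_bilstm_.state_dict(),
            "emission_head": self.emission_head_.state_dict(),
        }
        flat = {f"{g}.{k}": v for g, d in state.items() for k, v in d.items()}
        flat["transitions"] = self.transitions_.data
        flat["start_scores"] = self.start_scores_.data
        flat["end_scores"] = self.end_scores_.data
        np.savez(path, **flat)
        sidecar = {
            "params": self.get_params(),
            "vocab": self.vocab_,
            "label_words": self.label_word_map_.words,
        }
        Path(str(path) + ".json").write_text(
            json.dumps(sidecar, ensure_ascii=False, indent=1), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "TemplateFCTagger":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text(encoding="utf-8"))
        model = cls(**sidecar["params"])
        model.vocab_ = {k: int(v) for k, v in sidecar["vocab"].items()}
        model.tag_index_ = {t: i for i, t in enumerate(TAGS)}
        model.label_word_map_ = LabelWordMap(sidecar["label_words"])
        rng = np.random.default_rng(model.seed)
        model.encoder_ = TinyEncoder(len(model.vocab_), model.embed_dim, model.enc_hidden, rng)
        model.emission_bilstm_ = nn.BiLSTM(2 * model.enc_hidden, model.lstm_hidden, rng)
        model.emission_head_ = nn.Linear(2 * model.lstm_hidden, len(TAGS), rng)
        npz = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        model.encoder_.load_state_dict(
            {k[len("encoder."):]: npz[k] for k in npz.files if k.startswith("encoder.")}
        )
        model.emission_bilstm_.load_state_dict(
            {k[len("emission_bilstm."):]: npz[k] for k in npz.files if k.startswith("emission_bilstm.")}
        )
        model.emission_head_.load_state_dict(
            {k[len("emission_head."):]: npz[k] for k in npz.files if k.startswith("emission_head.")}
        )
        model.transitions_ = Tensor(npz["transitions"], requires_grad=True)
        model.start_scores_ = Tensor(npz["start_scores"], requires_grad=True)
        model.end_scores_ = Tensor(npz["end_scores"], requires_grad=True)
        model.loss_trace_ = []
        return model
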