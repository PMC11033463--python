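import numpy as np
import pytest

from acukg.autodiff import Tensor
from acukg.bio import TAGS
from acukg.templatefc import (
    LabelWordMap,
    MissingTagError,
    TemplateFCTagger,
    TinyEncoder,
    build_target_ids,
    decode_argmax,
    entlm_loss,
    entlm_loss_t,
    select_label_words,
)


def uniform_encoder(vocab_size):
    """Encoder stub: uniform LM distributions, zero embeddings."""

    def enc(ids):
        n = len(ids)
        w = Tensor(np.zeros((n, 4)))
        log_probs = Tensor(np.full((n, vocab_size), -np.log(vocab_size)))
        return w, log_probs

    return enc


def fixed_encoder(dists):
    """Encoder stub returning the given per-position distributions."""

    def enc(ids):
        safe = np.clip(np.asarray(dists, dtype=float), 1e-300, None)
        return Tensor(np.zeros((len(ids), 4))), Tensor(np.log(safe))

    return enc


class TestLabelWordMap:
    def test_duplicate_label_words_rejected(self):
        with pytest.raises(ValueError):
            LabelWordMap({"B-DIS": ["炎"], "B-SYM": ["炎"]})

    def test_inverse_maps_word_to_tag(self):
        m = LabelWordMap({"B-DIS": ["炎"], "I-DIS": ["症"]})
        assert m.inverse() == {"炎": "B-DIS", "症": "I-DIS"}

    def test_json_round_trip(self):
        m = LabelWordMap({"B-DIS": ["炎"]})
        assert LabelWordMap.from_json(m.to_json()).words == m.words


class TestSelectLabelWords:
    def test_dominant_character_wins_data_search(self):
        # "炎" occupies 90% of B-DIS positions; frequency-agnostic encoder
        vocab = {"<unk>": 0, "炎": 1, "痛": 2, "甲": 3}
        corpus = []
        for _ in range(9):
            corpus.append(([1, 3], ["B-DIS", "O"]))
        corpus.append(([2, 3], ["B-DIS", "O"]))
        m = select_label_words(corpus, uniform_encoder(4), vocab, k=1, tags=["B-DIS"])
        assert m.words["B-DIS"] == ["炎"]

    def test_missing_tag_reported(self):
        vocab = {"<unk>": 0, "甲": 1}
        with pytest.raises(MissingTagError, match="B-FUN"):
            select_label_words(
                [([1], ["O"])], uniform_encoder(2), vocab, tags=["B-FUN"]
            )

    def test_label_words_distinct_across_tags(self):
        vocab = {"<unk>": 0, "炎": 1, "痛": 2, "麻": 3, "甲": 4}
        corpus = [
            ([1, 2], ["B-DIS", "I-DIS"]),
            ([1, 2], ["B-DIS", "I-DIS"]),
            ([3, 4], ["B-SYM", "O"]),
        ]
        m = select_label_words(
            corpus, uniform_encoder(5), vocab, k=1, tags=["B-DIS", "I-DIS", "B-SYM"]
        )
        flat = [w for ws in m.words.values() for w in ws]
        assert len(flat) == len(set(flat)) == 3

    def test_lm_probability_breaks_frequency_ties(self):
        # equal frequency; the encoder prefers word 2 at tag positions
        vocab = {"<unk>": 0, "甲": 1, "乙": 2}
        dists = [[0.1, 0.2, 0.7]]
        corpus = [([1], ["B-DIS"]), ([2], ["B-DIS"])]

        def enc(ids):
            return (
                Tensor(np.zeros((len(ids), 4))),
                Tensor(np.log(np.tile(dists, (len(ids), 1)))),
            )

        m = select_label_words(corpus, enc, vocab, k=1, tags=["B-DIS"])
        assert m.words["B-DIS"] == ["乙"]


class TestEntLMLoss:
    def test_certain_encoder_gives_zero_loss(self):
        m = LabelWordMap({"B-DIS": ["标"]})
        vocab = {"<unk>": 0, "标": 1, "甲": 2}
        dists = np.zeros((2, 3))
        dists[0, 1] = 1.0  # position 0 is B-DIS -> predicts 标
        dists[1, 2] = 1.0  # position 1 is O -> predicts 甲 itself
        loss = entlm_loss([2, 2], ["B-DIS", "O"], m, vocab, fixed_encoder(dists))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_cross_entropy(self):
        m = LabelWordMap({"B-DIS": ["标"]})
        vocab = {"<unk>": 0, "标": 1, "甲": 2}
        dists = np.array([[0.2, 0.5, 0.3], [0.1, 0.3, 0.6]])
        loss = entlm_loss([2, 2], ["B-DIS", "O"], m, vocab, fixed_encoder(dists))
        assert loss == pytest.approx(-(np.log(0.5) + np.log(0.6)))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        dists = rng.dirichlet(np.ones(5), size=4)
        targets = [1, 2, 0, 4]
        a = entlm_loss_t(Tensor(np.log(dists)), targets).item()
        perm = [2, 0, 3, 1]
        b = entlm_loss_t(Tensor(np.log(dists[perm])), [targets[i] for i in perm]).item()
        assert a == pytest.approx(b)


class TestTargetSequence:
    def test_differs_exactly_at_entity_positions(self):
        m = LabelWordMap({"B-DIS": ["标"], "I-DIS": ["记"]})
        vocab = {"<unk>": 0, "标": 1, "记": 2, "甲": 3, "乙": 4}
        x = [3, 4, 3]
        got = build_target_ids(x, ["B-DIS", "I-DIS", "O"], m, vocab)
        assert got == [1, 2, 3]
        assert [i for i, (a, b) in enumerate(zip(x, got)) if a != b] == [0, 1]

    def test_length_mismatch_rejected(self):
        m = LabelWordMap({})
        with pytest.raises(ValueError):
            build_target_ids([1], ["O", "O"], m, {})


class TestDecodeArgmax:
    def test_identity_prediction_is_outside(self):
        m = LabelWordMap({"B-DIS": ["标"]})
        vocab = {"<unk>": 0, "标": 1, "甲": 2}
        log_probs = np.log(np.array([[0.1, 0.2, 0.7]]))
        assert decode_argmax([2], log_probs, m, vocab) == ["O"]

    def test_label_word_prediction_maps_to_tag(self):
        m = LabelWordMap({"B-DIS": ["标"]})
        vocab = {"<unk>": 0, "标": 1, "甲": 2}
        log_probs = np.log(np.array([[0.1, 0.8, 0.1]]))
        assert decode_argmax([2], log_probs, m, vocab) == ["B-DIS"]

    def test_matches_per_position_argmax_oracle(self):
        rng = np.random.default_rng(1)
        m = LabelWordMap({"B-DIS": ["标"], "B-XW": ["穴"]})
        vocab = {"<unk>": 0, "标": 1, "穴": 2, "甲": 3, "乙": 4}
        inv = {1: "B-DIS", 2: "B-XW"}
        for _ in range(50):
            n = int(rng.integers(1, 8))
            x = [int(rng.integers(3, 5)) for _ in range(n)]
            dists = rng.dirichlet(np.ones(5), size=n)
            got = decode_argmax(x, np.log(dists), m, vocab)
            raw = []
            for i in range(n):
                pred = int(np.argmax(dists[i]))
                raw.append("O" if pred == x[i] else inv.get(pred, "O"))
            # oracle applies the same BIO repair
            from acukg.bio import bio_repair

            assert got == bio_repair(raw)


@pytest.fixture(scope="module")
def tiny_corpus():
    sents = ["患甲乙丙者多。", "乙丙可治丁。", "患丁戊者少。", "甲乙丙常见。"]
    tags = [
        ["O", "B-DIS", "I-DIS", "I-DIS", "O", "O", "O"],
        ["B-OPE", "I-OPE", "O", "O", "B-DIS", "O"],
        ["O", "B-DIS", "I-DIS", "O", "O", "O"],
        ["B-DIS", "I-DIS", "I-DIS", "O", "O", "O"],
    ]
    return sents, tags


class TestTraining:
    def test_same_seed_reproduces_final_loss(self, tiny_corpus):
        sents, tags = tiny_corpus
        a = TemplateFCTagger(seed=0, epochs=3, lstm_hidden=8, enc_hidden=8, embed_dim=8)
        b = TemplateFCTagger(seed=0, epochs=3, lstm_hidden=8, enc_hidden=8, embed_dim=8)
        a.fit(sents, tags)
        b.fit(sents, tags)
        assert a.loss_trace_ == b.loss_trace_

    def test_loss_decreases_on_tiny_fixture(self, tiny_corpus):
        sents, tags = tiny_corpus
        m = TemplateFCTagger(seed=0, epochs=10, lstm_hidden=8, enc_hidden=8, embed_dim=8)
        m.fit(sents, tags)
        assert m.loss_trace_[-1] < m.loss_trace_[0]

    def test_predict_shapes_and_tags_valid(self, tiny_corpus):
        sents, tags = tiny_corpus
        m = TemplateFCTagger(seed=0, epochs=2, lstm_hidden=8, enc_hidden=8, embed_dim=8)
        m.fit(sents, tags)
        for decode in ["viterbi", "argmax"]:
            m.decode = decode
            preds = m.predict(sents + [""])
            assert [len(p) for p in preds] == [len(s) for s in sents] + [0]
            assert all(t in TAGS for p in preds for t in p)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            TemplateFCTagger().fit([], [])

    def test_mismatched_tags_rejected(self):
        with pytest.raises(ValueError):
            TemplateFCTagger().fit(["甲乙"], [["O"]])

    def test_save_load_round_trip(self, tiny_corpus, tmp_path):
        sents, tags = tiny_corpus
        m = TemplateFCTagger(seed=0, epochs=2, lstm_hidden=8, enc_hidden=8, embed_dim=8)
        m.fit(sents, tags)
        m.save(tmp_path / "model.npz")
        back = TemplateFCTagger.load(tmp_path / "model.npz")
        assert back.predict(sents) == m.predict(sents)
        assert back.label_word_map_.words == m.label_word_map_.words

    def test_joint_loss_is_weighted_sum_of_components(self, tiny_corpus):
        sents, tags = tiny_corpus
        m = TemplateFCTagger(
            seed=0, epochs=1, lstm_hidden=8, enc_hidden=8, embed_dim=8,
            lm_weight=0.5, crf_weight=2.0,
        )
        m.fit(sents, tags)
        for sent, y in zip(sents, tags):
            parts = m.joint_loss(sent, y)
            assert parts["total"] == pytest.approx(
                0.5 * parts["lm"] + 2.0 * parts["crf"]
            )
            assert parts["lm"] >= 0 and parts["crf"] >= 0

    def test_zero_crf_weight_reduces_to_lm_loss(self, tiny_corpus):
        sents, tags = tiny_corpus
        m = TemplateFCTagger(
            seed=0, epochs=1, lstm_hidden=8, enc_hidden=8, embed_dim=8, crf_weight=0.0
        )
        m.fit(sents, tags)
        parts = m.joint_loss(sents[0], tags[0])
        assert parts["total"] == pytest.approx(parts["lm"])

    def test_get_params_set_params(self):
        m = TemplateFCTagger(epochs=7)
        assert m.get_params()["epochs"] == 7
        m.set_params(lr=0.01)
        assert m.lr == 0.01


class TestEncoderContract:
    def test_output_lengths_and_normalized_distributions(self):
        rng = np.random.default_rng(2)
        enc = TinyEncoder(vocab_size=7, embed_dim=4, hidden=3, rng=rng)
        w, log_probs = enc([1, 2, 3, 4])
        assert w.shape == (4, 6)
        assert log_probs.shape == (4, 7)
        sums = np.exp(log_probs.data).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)


class TestAutodiffGradients:
    def test_lstm_chain_numeric_gradient(self):
        # numeric check through embedding -> BiLSTM -> linear -> scalar
        from acukg import nn

        rng = np.random.default_rng(3)
        emb = nn.Embedding(5, 3, rng)
        lstm = nn.BiLSTM(3, 2, rng)
        lin = nn.Linear(4, 1, rng)
        ids = [0, 2, 4]

        def forward():
            return lin(lstm(emb(ids))).sum()

        loss = forward()
        loss.backward()
        p = lstm.fwd.w_x
        got = p.grad.copy()
        eps = 1e-6
        for idx in [(0, 0), (1, 3), (2, 7)]:
            orig = p.data[idx]
            p.data[idx] = orig + eps
            up = forward().item()
            p.data[idx] = orig - eps
            down = forward().item()
            p.data[idx] = orig
            assert got[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)
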