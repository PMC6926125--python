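import math

import numpy as np
import pytest

from lpivec import (
    Alphabet,
    Sequence,
    SkipGramModel,
    TokenizedSequence,
    TrainingConfig,
    corpus_objective,
    embed_sequence,
    load_model,
    save_model,
    softmax_probability,
    train,
)
from lpivec.embedding import objective_gradients


def make_model(words, vin, vout=None, window=5):
    return SkipGramModel(words, vin, vout, TrainingConfig(dim=np.asarray(vin).shape[1], window=window))


class TestSoftmax:
    def test_zero_vectors_give_uniform(self):
        m = make_model(list("ACGU"), np.zeros((4, 3)))
        for center in "ACGU":
            for target in "ACGU":
                assert softmax_probability(m, center, target) == pytest.approx(0.25)

    def test_two_word_logits_hand_value(self):
        # center w0 with v = e1; outputs v'_0 = e1, v'_1 = 0 -> logits (1, 0)
        vin = np.array([[1.0], [0.0]])
        vout = np.array([[1.0], [0.0]])
        m = make_model(["w0", "w1"], vin, vout)
        assert softmax_probability(m, "w0", "w0") == pytest.approx(math.e / (math.e + 1), abs=1e-9)
        assert softmax_probability(m, "w0", "w1") == pytest.approx(1 / (math.e + 1), abs=1e-9)

    def test_normalization_over_targets(self, rng):
        words = [f"w{i}" for i in range(7)]
        m = make_model(words, rng.normal(size=(7, 5)), rng.normal(size=(7, 5)))
        for center in words:
            total = sum(softmax_probability(m, center, t) for t in words)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_out_of_vocabulary_rejected(self):
        m = make_model(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(KeyError):
            softmax_probability(m, "a", "zz")


class TestObjective:
    def test_two_token_sentence_uniform_model(self):
        m = make_model(list("ACGU"), np.zeros((4, 3)))
        corpus = [TokenizedSequence("x", ("A", "C"), 0)]
        assert corpus_objective(m, corpus) == pytest.approx(math.log(0.25), abs=1e-12)

    def test_single_token_sentence_warns_and_returns_zero(self):
        m = make_model(list("AC"), np.zeros((2, 2)))
        with pytest.warns(UserWarning):
            assert corpus_objective(m, [TokenizedSequence("x", ("A",), 0)]) == 0.0

    def test_empty_corpus_rejected(self):
        m = make_model(list("AC"), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            corpus_objective(m, [])

    def test_always_nonpositive_and_sentence_permutation_invariant(self, rng):
        words = [f"w{i}" for i in range(5)]
        m = make_model(words, rng.normal(size=(5, 4)), rng.normal(size=(5, 4)), window=2)
        corpus = [
            TokenizedSequence(f"s{i}", tuple(rng.choice(words, size=int(rng.integers(2, 8)))), 0)
            for i in range(6)
        ]
        obj = corpus_objective(m, corpus)
        assert obj <= 0
        assert corpus_objective(m, corpus[::-1]) == pytest.approx(obj, abs=1e-12)

    def test_analytic_gradient_matches_central_differences(self, rng):
        words = [f"w{i}" for i in range(6)]
        m = make_model(words, rng.normal(0, 0.3, (6, 4)), rng.normal(0, 0.3, (6, 4)), window=2)
        corpus = [TokenizedSequence("g", tuple(rng.choice(words, size=10)), 0)]
        d_in, d_out = objective_gradients(m, corpus)
        eps = 1e-6
        for table, grad in ((m.input_vectors, d_in), (m.output_vectors, d_out)):
            for i in range(table.shape[0]):
                for j in range(table.shape[1]):
                    orig = table[i, j]
                    table[i, j] = orig + eps
                    f_plus = corpus_objective(m, corpus)
                    table[i, j] = orig - eps
                    f_minus = corpus_objective(m, corpus)
                    table[i, j] = orig
                    fd = (f_plus - f_minus) / (2 * eps)
                    assert grad[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestTrain:
    def test_training_improves_objective(self, tiny_corpus, tiny_model):
        cfg = tiny_model.config
        rng = np.random.default_rng(cfg.seed)
        init = SkipGramModel(
            tiny_model.words,
            (rng.random((tiny_model.vocab_size, cfg.dim)) - 0.5) / cfg.dim,
            np.zeros((tiny_model.vocab_size, cfg.dim)),
            cfg,
        )
        assert corpus_objective(tiny_model, tiny_corpus) > corpus_objective(init, tiny_corpus)

    def test_min_count_one_keeps_singleton_word(self):
        corpus = [
            TokenizedSequence("a", ("AAAA", "AAAC", "AAAA", "AAAC"), 0),
            TokenizedSequence("b", ("AAAA", "AACA"), 0),  # AACA occurs once
        ]
        model = train(corpus, TrainingConfig(dim=4, epochs=2, min_count=1, seed=0))
        assert "AACA" in model.word_index

    def test_min_count_filters_rare_words(self):
        corpus = [
            TokenizedSequence("a", ("AAAA", "AAAC", "AAAA", "AAAC"), 0),
            TokenizedSequence("b", ("AAAA", "AACA"), 0),
        ]
        model = train(corpus, TrainingConfig(dim=4, epochs=2, min_count=2, seed=0))
        assert "AACA" not in model.word_index

    def test_deterministic_given_seed(self, tiny_corpus):
        cfg = TrainingConfig(dim=6, epochs=5, seed=42)
        m1 = train(tiny_corpus, cfg)
        m2 = train(tiny_corpus, cfg)
        assert np.array_equal(m1.input_vectors, m2.input_vectors)
        assert np.array_equal(m1.output_vectors, m2.output_vectors)

    def test_negative_sampling_deterministic_and_trains(self, tiny_corpus):
        cfg = TrainingConfig(dim=6, epochs=5, seed=42, negative=3)
        m1 = train(tiny_corpus, cfg)
        m2 = train(tiny_corpus, cfg)
        assert np.array_equal(m1.input_vectors, m2.input_vectors)
        assert np.isfinite(m1.input_vectors).all()
        # vectors actually moved off their initialisation
        assert np.abs(m1.output_vectors).max() > 0

    def test_degenerate_single_word_corpus_rejected(self):
        corpus = [TokenizedSequence("a", ("AAAA", "AAAA"), 0)]
        with pytest.raises(ValueError, match="degenerate"):
            train(corpus, TrainingConfig(dim=4))

    def test_vocabulary_is_sorted(self, tiny_model):
        assert tiny_model.words == sorted(tiny_model.words)


class TestEmbedSequence:
    def test_single_token_equals_its_vector(self, tiny_model):
        seq = Sequence("one", "AAAA", Alphabet.RNA)
        emb = embed_sequence(tiny_model, seq, 4)
        assert np.allclose(emb.vector, tiny_model.vector("AAAA"))
        assert emb.oov_count == 0

    def test_repeated_token_summation(self, tiny_model):
        seq = Sequence("rep", "AAAAA", Alphabet.RNA)  # two AAAA windows
        emb = embed_sequence(tiny_model, seq, 4)
        assert np.allclose(emb.vector, 2 * tiny_model.vector("AAAA"))

    def test_all_oov_gives_zero_vector(self, tiny_model):
        seq = Sequence("oov", "GGGGG", Alphabet.RNA)
        emb = embed_sequence(tiny_model, seq, 4)
        assert np.array_equal(emb.vector, np.zeros(tiny_model.dim))
        assert emb.oov_count == 2

    def test_token_multiset_determines_embedding(self, tiny_model):
        # the embedding is a sum over tokens, so permuting the token order
        # of the summation cannot change it
        from lpivec import segment

        tokens = segment(Sequence("a", "AAACAAAC", Alphabet.RNA), 4).tokens
        in_vocab = [t for t in tokens if t in tiny_model.word_index]
        forward = sum(tiny_model.vector(t) for t in in_vocab)
        backward = sum(tiny_model.vector(t) for t in reversed(in_vocab))
        emb = embed_sequence(tiny_model, Sequence("a", "AAACAAAC", Alphabet.RNA), 4)
        assert np.allclose(forward, backward)
        assert np.allclose(emb.vector, forward)

    def test_too_short_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            embed_sequence(tiny_model, Sequence("s", "AUG", Alphabet.RNA), 4)


class TestPersistence:
    def test_roundtrip_within_tolerance(self, tmp_path, rng):
        m = make_model(["AA", "AC", "CA", "CC"], rng.normal(size=(4, 3)))
        path = tmp_path / "model.w2v"
        save_model(m, path)
        back = load_model(path)
        assert back.words == m.words  # word order preserved
        assert np.allclose(back.input_vectors, m.input_vectors, atol=1e-6)

    def test_dimension_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.w2v"
        path.write_text("1 300\nAAAA " + " ".join(["0.0"] * 299) + "\n")
        with pytest.raises(ValueError, match="300"):
            load_model(path)

    def test_word_count_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.w2v"
        path.write_text("2 2\nAA 0.0 0.0\n")
        with pytest.raises(ValueError):
            load_model(path)
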