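import numpy as np
import pytest

from notemia import corpus_synth as cs
from notemia import experiments as ex
from notemia import icd_classifier as ic
from notemia import metrics
from notemia.errors import ValidationError


class TestVectorize:
    vocab = {"<pad>": 0, "<unk>": 1, "chest": 2, "pain": 3}

    def test_truncates_to_first_tokens(self):
        ids = ic.vectorize_note("chest pain chest pain chest", self.vocab, 3)
        np.testing.assert_array_equal(ids, [2, 3, 2])

    def test_unknown_token_maps_to_reserved_id(self):
        np.testing.assert_array_equal(
            ic.vectorize_note("chest zzz", self.vocab, 10), [2, 1]
        )

    def test_cap_beyond_length_keeps_everything(self):
        np.testing.assert_array_equal(
            ic.vectorize_note("chest pain", self.vocab, 100), [2, 3]
        )

    def test_empty_text_gives_single_padding_id(self):
        np.testing.assert_array_equal(ic.vectorize_note("", self.vocab, 10), [0])

    def test_vocabulary_ranks_by_frequency_then_lexicographic(self):
        vocab = ic.build_vocabulary(["b b a a c"], vocab_size=5)
        assert vocab["a"] == 2 and vocab["b"] == 3 and vocab["c"] == 4


class TestLabelAttention:
    def _params(self, hidden=6, att=4, labels=3, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "W_att": rng.normal(size=(hidden, att)),
            "U_att": rng.normal(size=(att, labels)),
        }

    def test_attention_weights_sum_to_one_per_label(self):
        rng = np.random.default_rng(1)
        hidden_states = rng.normal(size=(9, 6))
        _, attn = ic.label_attention(hidden_states, self._params())
        np.testing.assert_allclose(attn.sum(axis=0), np.ones(3), atol=1e-12)

    def test_single_token_vector_equals_hidden_state(self):
        rng = np.random.default_rng(2)
        hidden_states = rng.normal(size=(1, 6))
        vectors, _ = ic.label_attention(hidden_states, self._params())
        for row in vectors:
            np.testing.assert_allclose(row, hidden_states[0])

    def test_output_shape_independent_of_token_count(self):
        params = self._params()
        for t in (1, 5, 40):
            vectors, attn = ic.label_attention(np.ones((t, 6)), params)
            assert vectors.shape == (3, 6)
            assert attn.shape == (t, 3)

    def test_zero_length_input_rejected(self):
        with pytest.raises(ValidationError):
            ic.label_attention(np.empty((0, 6)), self._params())


def _tiny_setup(seed=0, epochs=3):
    universe = cs.build_code_universe(n_codes=6, phrases_per_code=2, seed=3)
    config = cs.CorpusConfig(
        n_notes=80, n_codes=6, mean_codes_per_note=2.0,
        note_length_tokens=(20, 30), seed=4,
    )
    corpus = cs.generate_corpus(universe, config)
    train, val, test = ex.split_corpus(corpus)
    classifier_config = ic.ClassifierConfig(
        n_labels=6, max_note_tokens=48, epochs=epochs, seed=seed
    )
    return universe, train, val, test, classifier_config


class TestTraining:
    def test_same_seed_reproduces_loss_trajectory_and_predictions(self):
        universe, train, val, test, config = _tiny_setup()
        m1 = ic.train_classifier(train, val, universe, config)
        m2 = ic.train_classifier(train, val, universe, config)
        assert m1.training_log == m2.training_log
        np.testing.assert_array_equal(
            ic.predict_probabilities(m1, test), ic.predict_probabilities(m2, test)
        )

    def test_label_outside_universe_rejected(self):
        universe, train, val, _test, config = _tiny_setup()
        rogue = cs.Note("rogue", "some text", frozenset({"dx_999"}), "train")
        with pytest.raises(ValidationError, match="dx_999"):
            ic.train_classifier(train + [rogue], val, universe, config)

    def test_signature_fixture_reaches_high_micro_f1(
        self, universe20, signature_corpus, trained_victim
    ):
        _train, _val, test = ex.split_corpus(signature_corpus)
        probs = ic.predict_probabilities(trained_victim, test)
        y = ex._label_matrix(test, trained_victim.label_codes)
        report = metrics.micro_macro_report(y, probs, ks=(1,))
        assert report.micro_f1 >= 0.80

    def test_utility_degrades_as_notes_are_truncated(self):
        """Mean test micro-F1 is non-increasing in the truncation cap."""
        universe = cs.build_code_universe(n_codes=8, phrases_per_code=2, seed=5)
        corpus = cs.generate_corpus(
            universe,
            cs.CorpusConfig(
                n_notes=150, n_codes=8, mean_codes_per_note=2.0,
                note_length_tokens=(48, 64), seed=6,
            ),
        )
        train, val, test = ex.split_corpus(corpus)
        y = ex._label_matrix(test, tuple(s.code for s in universe))
        means = []
        for cap in (64, 16, 4):
            f1s = []
            for seed in range(5):
                config = ic.ClassifierConfig(
                    n_labels=8, max_note_tokens=cap, epochs=8, seed=seed
                )
                model = ic.train_classifier(train, val, universe, config)
                probs = ic.predict_probabilities(model, test)
                f1s.append(metrics.micro_macro_report(y, probs, ks=(1,)).micro_f1)
            means.append(np.mean(f1s))
        assert means[0] >= means[1] >= means[2]


class TestPrediction:
    def test_probabilities_in_unit_interval(self, trained_victim, signature_corpus):
        probs = ic.predict_probabilities(trained_victim, signature_corpus[:30])
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_note_order_permutation_permutes_rows(self, trained_victim, signature_corpus):
        notes = signature_corpus[:20]
        base = ic.predict_probabilities(trained_victim, notes)
        perm = np.random.default_rng(0).permutation(20)
        permuted = ic.predict_probabilities(trained_victim, [notes[i] for i in perm])
        np.testing.assert_array_equal(permuted, base[perm])

    def test_prediction_independent_of_batch_size(self, trained_victim, signature_corpus):
        notes = signature_corpus[:30]
        a = ic.predict_probabilities(trained_victim, notes, batch_size=4)
        b = ic.predict_probabilities(trained_victim, notes, batch_size=30)
        np.testing.assert_array_equal(a, b)


class TestSerialization:
    def test_reloaded_model_predicts_bit_identically(
        self, tmp_path, trained_victim, signature_corpus
    ):
        path = tmp_path / "model.bin"
        ic.save_classifier(trained_victim, path)
        reloaded = ic.load_classifier(path)
        notes = signature_corpus[:25]
        np.testing.assert_array_equal(
            ic.predict_probabilities(trained_victim, notes),
            ic.predict_probabilities(reloaded, notes),
        )
        assert reloaded.label_codes == trained_victim.label_codes
        assert reloaded.vocabulary == trained_victim.vocabulary

    def test_saved_file_is_byte_stable(self, tmp_path, trained_victim):
        p1, p2 = tmp_path / "a.bin", tmp_path / "b.bin"
        ic.save_classifier(trained_victim, p1)
        ic.save_classifier(trained_victim, p2)
        assert p1.read_bytes() == p2.read_bytes()
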