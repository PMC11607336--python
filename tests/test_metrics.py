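import numpy as np
import pytest

from oracles import (
    macro_prf,
    max_advantage,
    micro_counts,
    pairwise_auc,
    precision_at_k_oracle,
    prf,
)

from notemia import metrics
from notemia.errors import ValidationError


class TestMicroMacroReport:
    def test_perfect_predictions_score_one(self):
        rng = np.random.default_rng(0)
        y = (rng.random((15, 6)) < 0.5).astype(int)
        y[0] = 1  # every label has a positive ...
        y[1] = 0  # ... and a negative
        report = metrics.micro_macro_report(y, y.astype(float), ks=(1,))
        assert report.micro_f1 == 1.0
        assert report.micro_auc == 1.0
        assert report.macro_precision == 1.0
        assert report.macro_auc == 1.0

    def test_micro_values_match_pooled_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = (rng.random((20, 5)) < 0.35).astype(int)
            y[0] = 1
            y[1] = 0
            probs = rng.random((20, 5))
            report = metrics.micro_macro_report(y, probs, threshold=0.5, ks=(1,))
            pred = (probs >= 0.5).astype(int)
            p, r, f1 = prf(*micro_counts(y.tolist(), pred.tolist()))
            assert report.micro_precision == pytest.approx(p, abs=1e-9)
            assert report.micro_recall == pytest.approx(r, abs=1e-9)
            assert report.micro_f1 == pytest.approx(f1, abs=1e-9)
            assert report.micro_auc == pytest.approx(
                pairwise_auc(y.ravel().tolist(), probs.ravel().tolist()), abs=1e-9
            )
            mp, mr, mf1 = macro_prf(y.tolist(), pred.tolist())
            assert report.macro_precision == pytest.approx(mp, abs=1e-9)
            assert report.macro_recall == pytest.approx(mr, abs=1e-9)
            assert report.macro_f1 == pytest.approx(mf1, abs=1e-9)

    def test_constant_probabilities_give_half_auc(self):
        y = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        probs = np.full((4, 2), 0.3)
        report = metrics.micro_macro_report(y, probs, ks=(1,))
        assert report.micro_auc == pytest.approx(0.5)

    def test_single_class_labels_excluded_from_macro_auc(self):
        y = np.array([[1, 0], [1, 0], [0, 0], [1, 0]])
        probs = np.array([[0.9, 0.2], [0.8, 0.1], [0.1, 0.3], [0.7, 0.2]])
        report = metrics.micro_macro_report(y, probs, ks=(1,))
        assert report.n_labels_excluded_from_macro_auc == 1
        assert report.macro_auc == 1.0  # only the informative label remains

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            metrics.micro_macro_report(np.zeros((3, 2)), np.zeros((3, 3)))

    def test_label_permutation_invariance_of_micro_metrics(self):
        rng = np.random.default_rng(5)
        y = (rng.random((12, 6)) < 0.4).astype(int)
        y[0] = 1
        y[1] = 0
        probs = rng.random((12, 6))
        perm = rng.permutation(6)
        a = metrics.micro_macro_report(y, probs, ks=(1,))
        b = metrics.micro_macro_report(y[:, perm], probs[:, perm], ks=(1,))
        assert a.micro_f1 == pytest.approx(b.micro_f1)
        assert a.micro_auc == pytest.approx(b.micro_auc)
        assert a.macro_f1 == pytest.approx(b.macro_f1)


class TestPrecisionAtK:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            y = (rng.random((10, 8)) < 0.4).astype(int)
            probs = rng.random((10, 8))
            got = metrics.precision_at_k(y, probs, ks=(1, 3, 5, 8))
            for k, value in got.items():
                assert value == pytest.approx(
                    precision_at_k_oracle(y.tolist(), probs.tolist(), k), abs=1e-9
                )

    def test_note_with_no_true_labels_contributes_zero(self):
        y = np.array([[0, 0, 0], [1, 1, 1]])
        probs = np.array([[0.9, 0.5, 0.1], [0.9, 0.5, 0.1]])
        assert metrics.precision_at_k(y, probs, ks=(2,))[2] == pytest.approx(0.5)

    def test_k_beyond_label_count_rejected(self):
        with pytest.raises(ValidationError):
            metrics.precision_at_k(np.zeros((2, 3)), np.zeros((2, 3)), ks=(4,))

    def test_probability_ties_break_by_label_index(self):
        y = np.array([[0, 1, 0]])
        probs = np.array([[0.5, 0.5, 0.5]])
        assert metrics.precision_at_k(y, probs, ks=(1,))[1] == 0.0


class TestAttackMetrics:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        result = metrics.attack_metrics(scores, labels)
        assert result.advantage == 1.0
        assert result.auc == 1.0

    def test_constant_scores_are_uninformative(self):
        result = metrics.attack_metrics(np.full(10, 0.5), np.array([1] * 5 + [0] * 5))
        assert result.advantage == 0.0
        assert result.auc == 0.5

    def test_matches_threshold_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            scores = np.round(rng.random(6), 1)  # force ties
            labels = np.array([1, 1, 1, 0, 0, 0])
            result = metrics.attack_metrics(scores, labels)
            assert result.advantage == pytest.approx(
                max_advantage(scores.tolist(), labels.tolist()), abs=1e-9
            )
            assert result.auc == pytest.approx(
                pairwise_auc(labels.tolist(), scores.tolist()), abs=1e-9
            )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        base = metrics.attack_metrics(scores, labels)
        warped = metrics.attack_metrics(np.exp(3 * scores), labels)
        assert base.auc == pytest.approx(warped.auc)
        assert base.advantage == pytest.approx(warped.advantage)

    def test_advantage_bounds(self):
        rng = np.random.default_rng(6)
        for seed in range(20):
            scores = rng.random(30)
            labels = (rng.random(30) < 0.4).astype(int)
            labels[0], labels[1] = 0, 1
            result = metrics.attack_metrics(scores, labels)
            assert 0.0 <= result.advantage <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            metrics.attack_metrics(np.array([0.1, 0.2]), np.array([1, 1]))
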