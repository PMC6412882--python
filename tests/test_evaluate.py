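"""Evaluation-framework tests: score matrix, condition loss, cosine scoring,
band labels, and the trained evaluator's ordering behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rehabsense.evaluate import (EvalHeads, EvalTrainConfig, LossWeights,
                                 build_lstm_classifier, build_score_matrix,
                                 condition_loss, cosine_score,
                                 evaluate_sample, learn_general_features,
                                 prediction_loss, resize_signal,
                                 score_dataset, score_to_label, total_loss,
                                 train_evaluation_model)
from rehabsense.nn import Tensor


class TestScoreMatrix:
    def test_is_identity_for_4x3(self):
        S = build_score_matrix(4, 3)
        np.testing.assert_array_equal(S, np.eye(12))

    def test_index_formula_corners(self):
        # (m=0,l=0) -> 0 and (m=3,l=2) -> 11 stay inside P=12
        S = build_score_matrix(4, 3)
        assert S[0, 0] == 1.0 and S[11, 11] == 1.0

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            build_score_matrix(0, 3)


class TestConditionLoss:
    def test_orthonormal_square_inverse_gives_zero(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        S = np.eye(12)
        assert condition_loss(Q.T, Q, S) == pytest.approx(0.0, abs=1e-18)

    def test_zero_G_gives_norm_of_S(self):
        S = build_score_matrix(4, 3)
        assert condition_loss(np.zeros((12, 8)), np.zeros((8, 12)), S) \
            == pytest.approx(12.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            condition_loss(np.zeros((12, 8)), np.zeros((9, 12)), np.eye(12))

    def test_learned_G_is_least_squares_minimizer(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(8, 12))
        S = build_score_matrix(4, 3)
        G = learn_general_features(C, S)
        # direct least-squares oracle via pseudo-inverse
        G_oracle = S @ np.linalg.pinv(C)
        assert np.allclose(G, G_oracle, atol=1e-6)
        base = condition_loss(G, C, S)
        for _ in range(100):
            G2 = G + rng.normal(0, 0.01, G.shape)
            assert condition_loss(G2, C, S) >= base - 1e-9

    def test_orthonormal_C_recovers_transpose(self):
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        G = learn_general_features(Q, np.eye(12))
        assert np.allclose(G, Q.T, atol=1e-8)

    def test_G_rows_classify_to_own_class(self):
        rng = np.random.default_rng(3)
        C = rng.normal(size=(24, 12))
        S = build_score_matrix(4, 3)
        G = learn_general_features(C, S)
        pred = (G @ C).argmax(axis=1)
        assert pred.tolist() == list(range(12))


class TestCosineScore:
    def test_parallel_orthogonal_antipodal(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_score(v, 5 * v) == pytest.approx(1.0)
        assert cosine_score([1, 0], [0, 1]) == pytest.approx(0.5)
        assert cosine_score(v, -v) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_score(np.zeros(3), np.ones(3))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        # arccos slope is unbounded at cos = +-1: allow for float rounding
        s1 = cosine_score(a, b)
        s2 = cosine_score(3.7 * a, 0.2 * b)
        assert s1 == pytest.approx(s2, abs=1e-6)
        assert 0.0 <= s1 <= 1.0


class TestScoreToLabel:
    @pytest.mark.parametrize("x,label", [
        (0.0, 0), (20.0, 0), (32.9, 0), (33.0, 1), (50.0, 1), (65.9, 1),
        (66.0, 2), (99.9, 2), (100.0, 2),
    ])
    def test_band_boundaries(self, x, label):
        assert score_to_label(x) == label

    def test_grid_partitions_without_gaps(self):
        labels = [score_to_label(x) for x in np.arange(0, 100.5, 0.5)]
        assert set(labels) == {0, 1, 2}
        assert labels == sorted(labels)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_to_label(-1.0)
        with pytest.raises(ValueError):
            score_to_label(101.0)


class TestLosses:
    def test_uniform_posterior_loss_is_log_P(self):
        logits = Tensor(np.zeros((1, 12)), requires_grad=True)
        loss = prediction_loss(logits, np.array([4]))
        assert float(loss.data) == pytest.approx(np.log(12))

    def test_one_hot_posterior_loss_near_zero(self):
        z = np.full((1, 12), -50.0)
        z[0, 7] = 50.0
        loss = prediction_loss(Tensor(z), np.array([7]))
        assert float(loss.data) < 1e-12

    def test_evaluation_loss_low_when_score_in_true_band(self):
        from rehabsense.evaluate import evaluation_loss
        # good sample (level 0) whose best score sits at the top band center
        scores = Tensor(np.array([[5.0 / 6.0, 0.2, 0.1]]), requires_grad=True)
        loss = evaluation_loss(scores, np.array([0]))
        assert float(loss.data) < 0.1

    def test_evaluation_loss_high_when_score_in_wrong_band(self):
        from rehabsense.evaluate import evaluation_loss
        # good sample scoring in the bottom band is penalized
        low = Tensor(np.array([[1.0 / 6.0, 0.1, 0.05]]), requires_grad=True)
        loss_bad = evaluation_loss(low, np.array([0]))
        assert float(loss_bad.data) > 1.0
        # and the gradient pushes the winning score upward
        loss_bad.backward()
        assert low.grad[0, 0] < 0

    def test_total_loss_weighting(self):
        assert total_loss(1.0, 1.0, 1.0, LossWeights(1, 1, 1)) == 3.0
        assert total_loss(2.0, 5.0, 7.0, LossWeights(1, 0, 0)) == 2.0

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0)
        with pytest.raises(ValueError):
            LossWeights(-1, 1, 1)


class TestEvaluateSample:
    def make_heads(self, seed=0):
        rng = np.random.default_rng(seed)
        G = rng.normal(size=(12, 8))
        return EvalHeads(C=rng.normal(size=(8, 12)), G=G,
                         S=build_score_matrix(4, 3), n_actions=4, n_levels=3)

    def test_exact_general_feature_scores_interval(self):
        heads = self.make_heads()
        q = evaluate_sample(heads.G[7], heads, predicted_action=2,
                            interval=100.0)
        assert q.evaluation == pytest.approx(100.0)
        assert q.level_label == 2

    def test_evaluation_in_range(self):
        heads = self.make_heads()
        rng = np.random.default_rng(4)
        for _ in range(50):
            q = evaluate_sample(rng.normal(size=8), heads, 1)
            assert 0.0 <= q.evaluation <= 100.0
            assert q.level_label in (0, 1, 2)

    def test_invalid_action_rejected(self):
        with pytest.raises(ValueError):
            evaluate_sample(np.ones(8), self.make_heads(), 7)


def test_resize_signal_endpoints_and_length():
    sig = np.column_stack([np.arange(10.0)] * 3)
    out = resize_signal(sig, 25)
    assert out.shape == (25, 3)
    assert out[0, 0] == 0.0 and out[-1, 0] == 9.0


class TestLstmClassifier:
    def test_forward_is_valid_posterior(self):
        from scipy.special import softmax
        cfg = EvalTrainConfig(lstm_dims=(8, 8, 6), dense_dims=(8, 6),
                              resize_len=16)
        m = build_lstm_classifier(4, 3, cfg, seed=0)
        out = m([Tensor(np.zeros((2, 16, 3)))]).data
        p = softmax(out, axis=1)
        assert p.shape == (2, 12)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_overfits_tiny_sample(self):
        rng = np.random.default_rng(5)
        cfg = EvalTrainConfig(lstm_dims=(16, 16, 12), dense_dims=(16, 12),
                              resize_len=20, epochs=200, batch_size=5,
                              lr=0.05, seed=0, weights=LossWeights(1, 0, 0))
        y_action = np.repeat(np.arange(4), 5)
        y_level = np.tile(np.arange(3), 7)[:20] * 0  # single level
        t = np.linspace(0, 1, 20)
        X = np.stack([
            np.sin(2 * np.pi * (a + 1) * t)[:, None] * np.ones((1, 3))
            + 0.01 * rng.normal(size=(20, 3))
            for a in y_action])
        model, heads, hist = train_evaluation_model(
            X, y_action, y_level, cfg, n_actions=4, n_levels=3)
        assert hist.accuracy[-1] == 1.0
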