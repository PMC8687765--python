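"""LSTM cell equations, bidirectional combination, loss, and gradients."""

import numpy as np
import pytest

from rhythmbeat import bilstm_core as bc
from rhythmbeat import heartbeat_dataset as hbd
from rhythmbeat import synthetic_ecg as se
from rhythmbeat.aami import AAMIClass


def scalar_cell(w=1.0, b=0.0):
    kw = {}
    for name in bc._CELL_FIELDS:
        kw[name] = (np.full((1, 1), w) if name[0] in "WU" else np.full(1, b))
    return bc.LSTMCellParams(**kw)


class TestCellStep:
    def test_zero_parameters(self):
        """All-zero weights: every gate is sigmoid(0)=0.5, candidate is 0,
        so C_t = 0.5 * C_prev and h_t = 0.5 * tanh(C_t)."""
        cell = scalar_cell(w=0.0)
        h, c = bc.lstm_cell_step(np.array([3.0]), np.array([0.7]),
                                 np.array([2.0]), cell)
        np.testing.assert_allclose(c, [1.0], atol=1e-15)
        np.testing.assert_allclose(h, [0.5 * np.tanh(1.0)], atol=1e-15)

    def test_scalar_hand_evaluation(self):
        """Unit weights, zero biases, x=0, h_prev=0, C_prev=1: gates are all
        sigmoid(0)=0.5, candidate tanh(0)=0, C_t=0.5, h_t=0.5*tanh(0.5)."""
        h, c = bc.lstm_cell_step(np.zeros(1), np.zeros(1), np.ones(1),
                                 scalar_cell(w=1.0))
        assert abs(c[0] - 0.5) < 1e-12
        assert abs(h[0] - 0.5 * np.tanh(0.5)) < 1e-12

    def test_hidden_state_bounded(self):
        """|h_t| <= 1 elementwise for any parameters and inputs."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            cell = bc.init_bilstm_params(4, 3, rng=rng).forward_cell
            scale = rng.uniform(0.1, 50)
            h, _ = bc.lstm_cell_step(scale * rng.standard_normal(4),
                                     rng.uniform(-1, 1, 3),
                                     scale * rng.standard_normal(3), cell)
            assert np.all(np.abs(h) <= 1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bc.lstm_cell_step(np.array([np.nan]), np.zeros(1), np.zeros(1),
                              scalar_cell())


class TestBidirectional:
    @pytest.mark.parametrize("t", [1, 5, 15])
    def test_output_count(self, t):
        p = bc.init_bilstm_params(6, 4, rng=np.random.default_rng(1))
        X = np.random.default_rng(2).standard_normal((t, 6))
        assert bc.bilstm_forward(X, p).shape == (t, 4)

    def test_pure_forward_degenerate(self):
        """Zero backward combination weight and bias: H_t is exactly the
        weighted forward hidden state."""
        rng = np.random.default_rng(3)
        p = bc.init_bilstm_params(5, 3, rng=rng)
        p.W_bwd_out[...] = 0.0
        p.b_comb[...] = 0.0
        X = rng.standard_normal((4, 5))
        H = bc.bilstm_forward(X, p)
        h = np.zeros(3)
        c = np.zeros(3)
        for t in range(4):
            h, c = bc.lstm_cell_step(X[t], h, c, p.forward_cell)
            np.testing.assert_allclose(H[t], p.W_fwd_out @ h, atol=1e-12)

    def test_reversal_symmetry(self):
        """Swapping the two cells and their output weights while reversing
        the input sequence reverses the outputs."""
        rng = np.random.default_rng(4)
        p = bc.init_bilstm_params(5, 3, rng=rng)
        X = rng.standard_normal((4, 5))
        swapped = bc.BiLSTMParams(
            forward_cell=p.backward_cell, backward_cell=p.forward_cell,
            W_fwd_out=p.W_bwd_out, W_bwd_out=p.W_fwd_out, b_comb=p.b_comb,
            head_W=p.head_W, head_b=p.head_b)
        np.testing.assert_allclose(bc.bilstm_forward(X, p),
                                   bc.bilstm_forward(X[::-1], swapped)[::-1],
                                   atol=1e-12)

    def test_concat_mode(self):
        rng = np.random.default_rng(5)
        p = bc.init_bilstm_params(5, 3, combine_mode="concat", rng=rng)
        X = rng.standard_normal((4, 5))
        assert bc.bilstm_forward(X, p).shape == (4, 6)
        probs = bc.classify_segment(X, p)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-9)


class TestClassify:
    def test_probabilities_normalised(self):
        rng = np.random.default_rng(6)
        p = bc.init_bilstm_params(7, 4, rng=rng)
        probs = bc.classify_segment(rng.standard_normal((5, 7)), p)
        assert probs.shape == (5, 5)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-9)

    def test_zero_head_uniform(self):
        p = bc.init_bilstm_params(7, 4, rng=np.random.default_rng(7))
        p.head_W[...] = 0.0
        p.head_b[...] = 0.0
        probs = bc.classify_segment(np.ones((3, 7)), p)
        np.testing.assert_allclose(probs, 0.2, atol=1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        p = bc.init_bilstm_params(7, 4, rng=rng)
        X = rng.standard_normal((3, 7))
        np.testing.assert_array_equal(bc.classify_segment(X, p),
                                      bc.classify_segment(X, p))


def _tiny_segments(labels, dim=6, seed=0, t=2, record="r"):
    rng = np.random.default_rng(seed)
    beats = [hbd.Beat(samples=rng.standard_normal(dim), label=lab,
                      r_index_in_window=0, source_record=record,
                      position_in_record=i)
             for i, lab in enumerate(labels)]
    return hbd.assemble_segments(beats, t)


class TestBaseLoss:
    def test_uniform_predictions_give_ln5(self):
        """Zero head -> uniform softmax -> cross-entropy ln 5 per beat."""
        p = bc.init_bilstm_params(6, 3, rng=np.random.default_rng(0))
        p.head_W[...] = 0.0
        p.head_b[...] = 0.0
        segs = _tiny_segments([AAMIClass.N, AAMIClass.V] * 3)
        cfg = bc.TrainConfig(lam=0.0)
        assert abs(bc.base_loss(segs, p, cfg) - np.log(5)) < 1e-12

    def test_confident_correct_gives_zero(self):
        p = bc.init_bilstm_params(6, 3, rng=np.random.default_rng(1))
        p.head_W[...] = 0.0
        p.head_b[...] = np.array([800.0, 0.0, 0.0, 0.0, 0.0])
        segs = _tiny_segments([AAMIClass.N] * 4)
        assert bc.base_loss(segs, p, bc.TrainConfig()) == 0.0

    def test_lambda_zero_is_pure_cross_entropy(self):
        rng = np.random.default_rng(2)
        p = bc.init_bilstm_params(6, 3, rng=rng)
        segs = _tiny_segments([AAMIClass.N, AAMIClass.S, AAMIClass.V] * 2)
        plain = bc.base_loss(segs, p, bc.TrainConfig(regularizer="none"))
        l1_off = bc.base_loss(segs, p, bc.TrainConfig(regularizer="L1", lam=0.0))
        assert plain == l1_off

    def test_penalties_add(self):
        rng = np.random.default_rng(3)
        p = bc.init_bilstm_params(6, 3, rng=rng)
        segs = _tiny_segments([AAMIClass.N] * 4)
        base = bc.base_loss(segs, p, bc.TrainConfig())
        l2 = bc.base_loss(segs, p, bc.TrainConfig(regularizer="L2", lam=0.5))
        assert abs(l2 - base - 0.5 * bc.penalty_l2(p)[0]) < 1e-10

    def test_empty_batch_rejected(self):
        p = bc.init_bilstm_params(6, 3, rng=np.random.default_rng(4))
        with pytest.raises(ValueError):
            bc.base_loss([], p, bc.TrainConfig())


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        """Analytic gradients of the cross-entropy match central finite
        differences to 1e-4 relative error on a tiny network."""
        rng = np.random.default_rng(0)
        D, H, T, B = 7, 3, 2, 2
        p = bc.init_bilstm_params(D, H, rng=rng)
        X = rng.standard_normal((B, T, D))
        y = rng.integers(0, 5, (B, T))
        _, grads, _ = bc.loss_and_grads(X, y, p)
        g = grads.flatten()
        flat = p.flatten()
        eps = 1e-5
        num = np.zeros_like(flat)
        for i in range(flat.size):
            f2 = flat.copy()
            f2[i] += eps
            p.set_flat(f2)
            cp, _, _ = bc.loss_and_grads(X, y, p)
            f2[i] -= 2 * eps
            p.set_flat(f2)
            cm, _, _ = bc.loss_and_grads(X, y, p)
            num[i] = (cp - cm) / (2 * eps)
        p.set_flat(flat)
        rel = np.abs(g - num) / np.maximum(np.abs(num), 1e-4)
        assert rel.max() < 1e-4


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        """Smoke property: five epochs on an easily separable N-vs-V set."""
        rng = np.random.default_rng(0)
        beats = []
        for i in range(120):
            lab = AAMIClass.N if i % 2 == 0 else AAMIClass.V
            beats.append(hbd.Beat(
                samples=se.generate_beat_waveform(lab, 360.0, rng),
                label=lab, r_index_in_window=90, source_record="r",
                position_in_record=i))
        segs = hbd.assemble_segments(beats, 4)
        cfg = bc.TrainConfig(epochs=5, batch_size=8, hidden_size=8,
                             learning_rate=3e-3, timestep=4, seed=0)
        _, history = bc.train_bilstm(segs, cfg)
        assert history[-1]["loss"] < history[0]["loss"]

    def test_training_is_seed_deterministic(self, bench_segments_t5):
        cfg = bc.TrainConfig(epochs=1, batch_size=32, hidden_size=6,
                             timestep=5, seed=3)
        segs = bench_segments_t5[:40]
        p1, h1 = bc.train_bilstm(segs, cfg)
        p2, h2 = bc.train_bilstm(segs, cfg)
        np.testing.assert_array_equal(p1.flatten(), p2.flatten())
        assert h1 == h2

    def test_predict_beats_aligned(self, bench_segments_t5):
        segs = bench_segments_t5[:30]
        p = bc.init_bilstm_params(235, 6, rng=np.random.default_rng(0))
        y_true, y_pred, probs = bc.predict_beats(segs, p)
        n = sum(len(s.beats) for s in segs)
        assert len(y_true) == len(y_pred) == len(probs) == n
        expected = [int(b.label) for s in segs for b in s.beats]
        assert y_true.tolist() == expected
        np.testing.assert_array_equal(probs.argmax(axis=1), y_pred)
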