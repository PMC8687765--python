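"""Distillation, average path length, the surrogate, and the joint loop."""

import dataclasses

import numpy as np
import pytest

from rhythmbeat import bilstm_core as bc
from rhythmbeat import tree_regularization as tr
from rhythmbeat.aami import AAMIClass
from rhythmbeat import heartbeat_dataset as hbd
from rhythmbeat import synthetic_ecg as se


def manual_tree(feature, threshold, left, right, value):
    n = len(feature)
    return tr.SimulatedDecisionTree(
        feature=np.asarray(feature), threshold=np.asarray(threshold, float),
        children_left=np.asarray(left), children_right=np.asarray(right),
        value=np.asarray(value, float),
        n_node_samples=np.asarray(value).sum(axis=1).astype(int))


class TestDistill:
    def test_constant_predictions_give_single_leaf(self):
        X = np.random.default_rng(0).standard_normal((50, 8))
        tree = tr.distill_tree(np.full(50, 2), X)
        assert tree.n_nodes == 1
        assert tree.fidelity == 1.0
        assert np.all(tree.predict(X) == 2)

    def test_threshold_separable_predictions(self):
        """A network implementing a single-feature threshold rule distils
        to a tree with near-perfect fidelity."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((600, 10))
        preds = (X[:, 3] > 0.25).astype(int) * 2  # classes {0, 2}
        tree = tr.distill_tree(preds, X, tr.TreeConstraints(min_samples_leaf=5))
        assert tree.fidelity >= 0.99

    def test_targets_are_predictions_not_ground_truth(self):
        """The distilled tree depends only on the network predictions;
        ground-truth labels never enter."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 5))
        preds = (X[:, 0] > 0).astype(int)
        t1 = tr.distill_tree(preds, X, seed=7)
        t2 = tr.distill_tree(preds, X, seed=7)  # "corrupted labels" unseen
        assert t1.to_json() == t2.to_json()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tr.distill_tree(np.empty(0, int), np.empty((0, 3)))

    def test_json_roundtrip(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 6))
        tree = tr.distill_tree((X[:, 1] > 0).astype(int), X)
        back = tr.SimulatedDecisionTree.from_json(tree.to_json())
        np.testing.assert_array_equal(back.predict(X), tree.predict(X))
        assert back.fidelity == tree.fidelity

    def test_dot_export(self):
        X = np.random.default_rng(4).standard_normal((100, 4))
        tree = tr.distill_tree((X[:, 0] > 0).astype(int), X)
        dot = tree.to_dot()
        assert dot.startswith("digraph") and "x[0]" in dot


class TestAveragePathLength:
    def test_single_leaf_is_zero(self):
        tree = manual_tree([-1], [0.0], [-1], [-1], [[10, 0, 0, 0, 0]])
        assert tr.average_path_length(tree, np.zeros((7, 3))) == 0.0

    def test_complete_depth_two(self):
        """Every sample traverses exactly 2 internal nodes."""
        tree = manual_tree(
            feature=[0, 1, 1, -1, -1, -1, -1],
            threshold=[0.0, 0.0, 0.0, 0, 0, 0, 0],
            left=[1, 3, 5, -1, -1, -1, -1],
            right=[2, 4, 6, -1, -1, -1, -1],
            value=[[4, 0, 0, 0, 0]] * 3 + [[1, 0, 0, 0, 0]] * 4)
        X = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]], dtype=float)
        assert tr.average_path_length(tree, X) == 2.0

    def test_unbalanced_hand_case(self):
        """Left child is a leaf (1 decision), right subtree needs 2:
        two samples each way -> (2*1 + 2*2)/4 = 1.5."""
        tree = manual_tree(
            feature=[0, -1, 0, -1, -1],
            threshold=[0.5, 0, 1.5, 0, 0],
            left=[1, -1, 3, -1, -1],
            right=[2, -1, 4, -1, -1],
            value=[[4, 0, 0, 0, 0], [2, 0, 0, 0, 0], [2, 0, 0, 0, 0],
                   [1, 0, 0, 0, 0], [1, 0, 0, 0, 0]])
        X = np.array([[0.0], [0.2], [1.0], [2.0]])
        assert tr.average_path_length(tree, X) == 1.5

    def test_empty_rejected(self):
        tree = manual_tree([-1], [0.0], [-1], [-1], [[1, 0, 0, 0, 0]])
        with pytest.raises(ValueError):
            tr.average_path_length(tree, np.empty((0, 2)))

    def test_matches_independent_walk(self):
        """Vectorised APL equals a per-sample pure-Python root-to-leaf walk
        on randomly grown trees."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            n, d = int(rng.integers(20, 120)), int(rng.integers(2, 6))
            X = rng.standard_normal((n, d))
            y = rng.integers(0, 5, n)
            tree = tr.distill_tree(
                y, X, tr.TreeConstraints(max_depth=int(rng.integers(1, 7)),
                                         min_samples_leaf=1),
                seed=int(rng.integers(1000)))
            Xq = rng.standard_normal((40, d))

            def walk(x):
                node = 0
                steps = 0
                while not tree.is_leaf(node):
                    node = (tree.children_left[node]
                            if x[tree.feature[node]] <= tree.threshold[node]
                            else tree.children_right[node])
                    steps += 1
                return steps

            expected = np.mean([walk(x) for x in Xq])
            assert tr.average_path_length(tree, Xq) == expected


class TestSurrogate:
    def test_recovers_linear_apl(self):
        """APL an exact (nonnegative) linear function of a 20-dim weight
        vector: held-out RMSE under 5% of the APL range."""
        rng = np.random.default_rng(0)
        W = rng.standard_normal((200, 20))
        beta = rng.normal(0, 0.25, 20)
        apl = 4.0 + W @ beta
        assert apl.min() > 0
        model = tr.train_surrogate(W, apl, iters=2000, seed=1)
        hold = slice(0, 40)
        pred = model.predict_batch(W[hold])
        rmse = np.sqrt(np.mean((pred - apl[hold]) ** 2))
        assert rmse < 0.05 * (apl.max() - apl.min())

    def test_huge_ridge_collapses_to_constant(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((60, 12))
        apl = 3.0 + np.abs(W[:, 0])
        model = tr.train_surrogate(W, apl, eps=1e6, iters=1500, seed=2)
        preds = model.predict_batch(W)
        assert np.var(preds) < 0.01 * np.var(apl)

    def test_scalar_output(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((20, 6))
        model = tr.train_surrogate(W, 2 + np.abs(W[:, 0]), iters=100)
        out = model.predict(W[0])
        assert isinstance(out, float) and out >= 0.0

    def test_degenerate_dataset_rejected(self):
        with pytest.raises(ValueError):
            tr.train_surrogate(np.zeros((1, 4)), np.zeros(1))

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        W = rng.standard_normal((40, 9))
        model = tr.train_surrogate(W, 2 + W[:, 0] ** 2, iters=300, seed=4)
        w = rng.standard_normal(9)
        g = model.grad_wrt_input(w)
        eps = 1e-6
        num = np.zeros(9)
        for i in range(9):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            num[i] = (model.predict(wp) - model.predict(wm)) / (2 * eps)
        np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-8)


class TestSurrogateDataset:
    def _factory(self, w):
        # deterministic pseudo-network: thresholds features by w's mean
        def predict(X):
            return (X[:, 0] > float(np.mean(w))).astype(int)
        return predict

    def test_pair_count(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 4))
        cks = [rng.standard_normal(10) for _ in range(3)]
        W, apl = tr.build_surrogate_dataset(
            cks, X, lambda w: self._factory(w)(X), n_perturbations=4,
            rng=np.random.default_rng(1))
        assert W.shape == (15, 10) and len(apl) == 15
        assert np.all(apl >= 0)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 4))
        cks = [rng.standard_normal(10)]
        out1 = tr.build_surrogate_dataset(cks, X,
                                          lambda w: self._factory(w)(X),
                                          rng=np.random.default_rng(9))
        out2 = tr.build_surrogate_dataset(cks, X,
                                          lambda w: self._factory(w)(X),
                                          rng=np.random.default_rng(9))
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_empty_checkpoints_rejected(self):
        with pytest.raises(ValueError):
            tr.build_surrogate_dataset([], np.zeros((5, 2)), lambda w: None)


def _tiny_segments(n=24, t=3, seed=0):
    rng = np.random.default_rng(seed)
    labels = [AAMIClass.N if i % 2 else AAMIClass.V for i in range(n)]
    beats = [hbd.Beat(samples=se.generate_beat_waveform(lab, 100.0, rng),
                      label=lab, r_index_in_window=25, source_record="r",
                      position_in_record=i) for i, lab in enumerate(labels)]
    return hbd.assemble_segments(beats, t)


class TestTregLoss:
    def test_constant_surrogate_adds_constant(self):
        segs = _tiny_segments()
        p = bc.init_bilstm_params(66, 4, rng=np.random.default_rng(0))
        cfg = bc.TrainConfig(regularizer="none", lam=0.0)
        base = bc.base_loss(segs, p, cfg)
        sur = tr.SurrogateModel.constant(2.5, dim=p.n_params)
        assert abs(tr.treg_loss(segs, p, sur, lam=1.0) - base - 2.5) < 1e-9
        assert tr.treg_loss(segs, p, sur, lam=0.0) == base

    def test_untrained_surrogate_rejected(self):
        segs = _tiny_segments()
        p = bc.init_bilstm_params(66, 4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            tr.treg_loss(segs, p, None, lam=1.0)


class TestJointTraining:
    def test_lambda_zero_matches_plain_training(self):
        """With lam=0 the distillation machinery runs for measurement only:
        final weights equal plain training with the same seed."""
        segs = _tiny_segments(n=36, t=3)
        cfg = bc.TrainConfig(epochs=4, batch_size=4, hidden_size=5,
                             timestep=3, regularizer="tree", lam=0.0, seed=7)
        sch = tr.TregSchedule(distill_every=2, n_perturbations=1,
                              lam=0.0, surrogate_iters=30, apl_sample_cap=200)
        p_treg, tree, hist = tr.train_bilstm_treg(segs, cfg, sch)
        plain_cfg = dataclasses.replace(cfg, regularizer="none", lam=0.0)
        p_plain, _ = bc.train_bilstm(segs, plain_cfg)
        np.testing.assert_array_equal(p_treg.flatten(), p_plain.flatten())
        assert tree is not None

    def test_history_has_one_entry_per_distill_interval(self):
        segs = _tiny_segments(n=36, t=3)
        cfg = bc.TrainConfig(epochs=6, batch_size=4, hidden_size=5,
                             timestep=3, regularizer="tree", lam=1.0, seed=1)
        sch = tr.TregSchedule(distill_every=2, n_perturbations=1,
                              lam=1.0, surrogate_iters=30, apl_sample_cap=200)
        _, _, hist = tr.train_bilstm_treg(segs, cfg, sch)
        distilled = [h for h in hist if "true_apl" in h]
        assert len(distilled) == 3  # epochs 2, 4, 6
        for h in distilled:
            assert h["true_apl"] >= 0.0
            assert 0.0 <= h["fidelity"] <= 1.0
            assert h["surrogate_apl"] >= 0.0
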