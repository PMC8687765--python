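"""Tree-regularized training of the beat classifier.

The idea: alongside gradient training of the network, repeatedly fit an
axis-aligned decision tree to the *network's own per-beat predictions*
(knowledge distillation — the tree's targets are the model outputs, never
the ground truth).  The complexity of that simulated decision tree (SDT),
measured as the average path length (APL) — the mean number of internal
decision nodes a sample traverses from root to leaf — becomes a penalty on
the network.  Because APL is not differentiable in the network weights, a
small MLP surrogate is trained on (weight-vector, true-APL) pairs collected
from training checkpoints and Gaussian perturbations of them; the surrogate
is differentiable, so ``loss = cross-entropy + lambda * surrogate(W)`` can
be optimised by gradient descent.

The distilled tree doubles as the interpretability artifact (see
:mod:`rhythmbeat.interpretability`).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .aami import CLASS_NAMES, N_CLASSES
from . import bilstm_core
from .bilstm_core import BiLSTMParams, TrainConfig

__all__ = [
    "SimulatedDecisionTree",
    "TreeConstraints",
    "SurrogateModel",
    "TregSchedule",
    "distill_tree",
    "average_path_length",
    "build_surrogate_dataset",
    "train_surrogate",
    "treg_loss",
    "train_bilstm_treg",
]


@dataclasses.dataclass(frozen=True)
class TreeConstraints:
    max_depth: int = 8
    min_samples_leaf: int = 20


@dataclasses.dataclass
class SimulatedDecisionTree:
    """Axis-aligned binary tree in flat-array form.

    ``feature[i] == -1`` marks a leaf; internal nodes hold a feature index
    into the beat window and an mV threshold (samples with
    ``x[feature] <= threshold`` go left).  ``value[i]`` tallies the class
    distribution of the fitting samples that reached node ``i``.
    """

    feature: np.ndarray          # (n_nodes,) int, -1 at leaves
    threshold: np.ndarray        # (n_nodes,) float
    children_left: np.ndarray    # (n_nodes,) int, -1 at leaves
    children_right: np.ndarray   # (n_nodes,) int, -1 at leaves
    value: np.ndarray            # (n_nodes, 5) float tallies
    n_node_samples: np.ndarray   # (n_nodes,) int
    fidelity: Optional[float] = None

    def __post_init__(self):
        self.feature = np.asarray(self.feature, dtype=int)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.children_left = np.asarray(self.children_left, dtype=int)
        self.children_right = np.asarray(self.children_right, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        self.n_node_samples = np.asarray(self.n_node_samples, dtype=int)
        internal = self.feature >= 0
        if np.any((self.children_left[internal] < 0)
                  | (self.children_right[internal] < 0)):
            raise ValueError("internal nodes need two children")
        if np.any(~np.isfinite(self.threshold[internal])):
            raise ValueError("internal thresholds must be finite")

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def is_leaf(self, i: int) -> bool:
        return bool(self.feature[i] < 0)

    def node_depths(self) -> np.ndarray:
        """Number of internal decision nodes above each node (root = 0)."""
        depths = np.zeros(self.n_nodes, dtype=int)
        stack = [0]
        while stack:
            i = stack.pop()
            if not self.is_leaf(i):
                for ch in (self.children_left[i], self.children_right[i]):
                    depths[ch] = depths[i] + 1
                    stack.append(ch)
        return depths

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index reached by each sample (vectorised level-wise descent)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        node = np.zeros(len(X), dtype=int)
        active = self.feature[node] >= 0
        while np.any(active):
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.children_left[cur],
                                 self.children_right[cur])
            active = self.feature[node] >= 0
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-sample class index = majority class of the reached leaf."""
        leaf = self.apply(X)
        return self.value[leaf].argmax(axis=1)

    @classmethod
    def from_sklearn(cls, clf: DecisionTreeClassifier,
                     n_classes: int = N_CLASSES) -> "SimulatedDecisionTree":
        t = clf.tree_
        value = np.zeros((t.node_count, n_classes))
        classes = np.asarray(clf.classes_, dtype=int)
        value[:, classes] = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
        return cls(feature=np.where(t.children_left < 0, -1, t.feature),
                   threshold=t.threshold.copy(),
                   children_left=t.children_left.copy(),
                   children_right=t.children_right.copy(),
                   value=value,
                   n_node_samples=t.n_node_samples.copy())

    def to_json(self) -> str:
        return json.dumps({
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "value": self.value.tolist(),
            "n_node_samples": self.n_node_samples.tolist(),
            "fidelity": self.fidelity,
        })

    @classmethod
    def from_json(cls, text: str) -> "SimulatedDecisionTree":
        d = json.loads(text)
        fid = d.pop("fidelity", None)
        tree = cls(**{k: np.asarray(v) for k, v in d.items()})
        tree.fidelity = fid
        return tree

    def to_dot(self) -> str:
        """Graphviz rendering with per-node class tallies."""
        lines = ["digraph SDT {", "  node [shape=box, fontsize=10];"]
        for i in range(self.n_nodes):
            tal = ", ".join(f"{n}:{int(v)}"
                            for n, v in zip(CLASS_NAMES, self.value[i]))
            if self.is_leaf(i):
                cls_name = CLASS_NAMES[int(self.value[i].argmax())]
                lines.append(f'  n{i} [label="leaf {cls_name}\\n{tal}"];')
            else:
                lines.append(
                    f'  n{i} [label="x[{self.feature[i]}] <= '
                    f'{self.threshold[i]:.4f}\\n{tal}"];')
                lines.append(f"  n{i} -> n{self.children_left[i]} "
                             f'[label="yes"];')
                lines.append(f"  n{i} -> n{self.children_right[i]} "
                             f'[label="no"];')
        lines.append("}")
        return "\n".join(lines)


def distill_tree(model_predictions, beat_features,
                 constraints: TreeConstraints = TreeConstraints(),
                 seed: int = 0) -> SimulatedDecisionTree:
    """Fit the SDT on (beat features, *network* predictions) and score fidelity.

    Fidelity = fraction of fitting samples where the tree reproduces the
    network's prediction.
    """
    y = np.asarray(model_predictions, dtype=int)
    X = np.atleast_2d(np.asarray(beat_features, dtype=float))
    if len(y) == 0 or len(X) != len(y):
        raise ValueError("need aligned, non-empty predictions and features")
    clf = DecisionTreeClassifier(max_depth=constraints.max_depth,
                                 min_samples_leaf=constraints.min_samples_leaf,
                                 random_state=seed)
    clf.fit(X, y)
    tree = SimulatedDecisionTree.from_sklearn(clf)
    tree.fidelity = float((tree.predict(X) == y).mean())
    return tree


def average_path_length(tree: SimulatedDecisionTree, X) -> float:
    """Mean number of internal decision nodes traversed root -> leaf."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(X) == 0:
        raise ValueError("empty sample matrix")
    depths = tree.node_depths()
    return float(depths[tree.apply(X)].mean())


def _softplus(x):
    return np.logaddexp(0.0, x)


@dataclasses.dataclass
class SurrogateModel:
    """One-hidden-layer MLP mapping a flat weight vector to predicted APL.

    tanh hidden layer, softplus output (so the prediction is nonnegative);
    inputs are centred on the training mean and scaled by a single global
    standard deviation.
    """

    A: np.ndarray          # (hidden, P)
    a: np.ndarray          # (hidden,)
    B: np.ndarray          # (1, hidden)
    b: np.ndarray          # (1,)
    mean: np.ndarray       # (P,)
    scale: float
    eps: float = 1e-3
    train_mse: Optional[float] = None
    holdout_mse: Optional[float] = None

    def _hidden(self, W2: np.ndarray) -> np.ndarray:
        U = (W2 - self.mean) / self.scale
        return np.tanh(U @ self.A.T + self.a)

    def predict_batch(self, W2: np.ndarray) -> np.ndarray:
        Z = self._hidden(np.atleast_2d(W2))
        return _softplus(Z @ self.B.T + self.b)[:, 0]

    def predict(self, w: np.ndarray) -> float:
        return float(self.predict_batch(np.asarray(w, dtype=float)[None])[0])

    def grad_wrt_input(self, w: np.ndarray) -> np.ndarray:
        """d predict / d w at one weight vector (analytic)."""
        w = np.asarray(w, dtype=float)
        u = (w - self.mean) / self.scale
        z = np.tanh(self.A @ u + self.a)
        pre = float((self.B @ z + self.b)[0])
        s = 1.0 / (1.0 + np.exp(-pre))  # softplus'
        return s * ((self.B[0] * (1.0 - z * z)) @ self.A) / self.scale

    @classmethod
    def constant(cls, c: float, dim: int, hidden: int = 25) -> "SurrogateModel":
        """A surrogate that predicts ``c`` for every input (testing aid)."""
        b = np.log(np.expm1(max(c, 1e-12)))
        return cls(A=np.zeros((hidden, dim)), a=np.zeros(hidden),
                   B=np.zeros((1, hidden)), b=np.array([b]),
                   mean=np.zeros(dim), scale=1.0)


def train_surrogate(dataset_W, dataset_apl, eps: float = 1e-3,
                    hidden: int = 25, iters: int = 800, lr: float = 1e-2,
                    seed: int = 0, holdout_frac: float = 0.2) -> SurrogateModel:
    """Ridge-regularised least-squares fit of the surrogate MLP.

    Minimises ``sum_j (APL_j - surrogate(W_j))^2 + eps * ||xi||^2`` over all
    MLP parameters xi with full-batch Adam.  With at least 10 pairs a random
    holdout is kept aside and its MSE reported on the returned model.
    """
    W = np.atleast_2d(np.asarray(dataset_W, dtype=float))
    apl = np.asarray(dataset_apl, dtype=float)
    J, P = W.shape
    if J < 2 or len(apl) != J:
        raise ValueError("need at least 2 aligned (W, APL) pairs")
    rng = np.random.default_rng(seed)
    if J >= 10 and holdout_frac > 0:
        n_hold = max(1, int(round(holdout_frac * J)))
        perm = rng.permutation(J)
        hold_idx, fit_idx = perm[:n_hold], perm[n_hold:]
    else:
        hold_idx, fit_idx = np.empty(0, int), np.arange(J)

    mean = W.mean(axis=0)
    scale = float(W.std()) or 1.0
    U = (W[fit_idx] - mean) / scale
    t = apl[fit_idx][:, None]

    A = rng.normal(0, 1.0 / np.sqrt(P), size=(hidden, P))
    a = np.zeros(hidden)
    B = rng.normal(0, 1.0 / np.sqrt(hidden), size=(1, hidden))
    b = np.array([np.log(np.expm1(max(t.mean(), 1e-6)))])

    theta = [A, a, B, b]
    m = [np.zeros_like(x) for x in theta]
    v = [np.zeros_like(x) for x in theta]
    b1, b2, aeps = 0.9, 0.999, 1e-8
    for it in range(1, iters + 1):
        Zpre = U @ A.T + a
        Z = np.tanh(Zpre)
        pre = Z @ B.T + b
        Y = _softplus(pre)
        r = Y - t
        dpre = 2.0 * r * (1.0 / (1.0 + np.exp(-pre)))
        gB = dpre.T @ Z + 2.0 * eps * B
        gb = dpre.sum(axis=0) + 2.0 * eps * b
        dZ = (dpre @ B) * (1.0 - Z * Z)
        gA = dZ.T @ U + 2.0 * eps * A
        ga = dZ.sum(axis=0) + 2.0 * eps * a
        for x, g, mm, vv in zip(theta, (gA, ga, gB, gb), m, v):
            mm *= b1
            mm += (1 - b1) * g
            vv *= b2
            vv += (1 - b2) * g * g
            x -= lr * (mm / (1 - b1 ** it)) / (np.sqrt(vv / (1 - b2 ** it)) + aeps)

    model = SurrogateModel(A=A, a=a, B=B, b=b, mean=mean, scale=scale, eps=eps)
    model.train_mse = float(np.mean((model.predict_batch(W[fit_idx])
                                     - apl[fit_idx]) ** 2))
    if len(hold_idx):
        model.holdout_mse = float(np.mean((model.predict_batch(W[hold_idx])
                                           - apl[hold_idx]) ** 2))
    return model


def build_surrogate_dataset(checkpoint_weights: Sequence[np.ndarray],
                            beat_features: np.ndarray,
                            model_factory: Callable[[np.ndarray], np.ndarray],
                            n_perturbations: int = 3,
                            noise_sd: float = 0.1,
                            rng: Optional[np.random.Generator] = None,
                            constraints: TreeConstraints = TreeConstraints()):
    """(W_j, true-APL_j) pairs from checkpoints plus Gaussian perturbations.

    ``model_factory(w)`` must return the network's per-beat predictions on
    ``beat_features`` for weight vector ``w``.  Each checkpoint contributes
    itself plus ``n_perturbations`` perturbed copies (per-parameter noise sd
    = ``noise_sd`` times the checkpoint's own weight sd), giving
    ``J = len(checkpoints) * (1 + n_perturbations)`` pairs.
    """
    if len(checkpoint_weights) == 0:
        raise ValueError("need at least one checkpoint")
    rng = rng if rng is not None else np.random.default_rng(0)
    X = np.atleast_2d(np.asarray(beat_features, dtype=float))
    Ws, apls = [], []
    for w in checkpoint_weights:
        w = np.asarray(w, dtype=float)
        sd = noise_sd * float(w.std())
        variants = [w] + [w + sd * rng.standard_normal(w.size)
                          for _ in range(n_perturbations)]
        for wv in variants:
            preds = np.asarray(model_factory(wv), dtype=int)
            tree = distill_tree(preds, X, constraints,
                                seed=int(rng.integers(2**31 - 1)))
            Ws.append(wv)
            apls.append(average_path_length(tree, X))
    return np.stack(Ws), np.asarray(apls)


def treg_loss(segments, p: BiLSTMParams, surrogate: SurrogateModel,
              lam: float, cfg: Optional[TrainConfig] = None) -> float:
    """Cross-entropy plus ``lam * surrogate(W)`` (differentiable in W)."""
    if surrogate is None:
        raise ValueError("surrogate model is not trained")
    base_cfg = cfg or TrainConfig(regularizer="none", lam=0.0)
    ce_cfg = dataclasses.replace(base_cfg, regularizer="none", lam=0.0)
    ce = bilstm_core.base_loss(segments, p, ce_cfg)
    return ce + lam * surrogate.predict(p.flatten())


@dataclasses.dataclass(frozen=True)
class TregSchedule:
    """When to distill, how to grow the surrogate dataset, how hard to push."""

    distill_every: int = 3
    n_perturbations: int = 3
    surrogate_retrain_every: int = 3
    lam: float = 10.0
    tree_constraints: TreeConstraints = TreeConstraints()
    noise_sd: float = 0.1
    surrogate_eps: float = 1e-3
    surrogate_hidden: int = 25
    surrogate_iters: int = 800
    apl_sample_cap: int = 5000

    def __post_init__(self):
        if min(self.distill_every, self.surrogate_retrain_every) < 1:
            raise ValueError("schedule intervals must be positive")
        if self.lam < 0 or self.n_perturbations < 0:
            raise ValueError("lam and n_perturbations must be >= 0")


def train_bilstm_treg(train_segments, cfg: TrainConfig,
                      schedule: TregSchedule):
    """Joint loop: gradient steps on the penalised loss, periodic distillation.

    Every ``distill_every`` epochs the current network's predictions are
    refreshed, an SDT distilled (true APL + fidelity logged), the surrogate
    dataset extended with the checkpoint and its perturbations, and the
    surrogate refit; from then on the penalty ``lam * surrogate(W)`` joins
    the loss.  With ``lam == 0`` the machinery still runs for measurement
    but the final weights match plain training with the same seed exactly
    (the distillation RNG stream is independent of the training stream).

    Returns ``(params, final SDT, history)``; distillation epochs carry
    ``true_apl``, ``surrogate_apl`` and ``fidelity`` entries in the history.
    """
    lam = schedule.lam if cfg.regularizer == "tree" else 0.0
    rng_treg = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7269]))

    # fixed distillation subset: whole segments, capped at ~apl_sample_cap beats
    seg_order = rng_treg.permutation(len(train_segments))
    sub_segments = []
    n_sub = 0
    for i in seg_order:
        sub_segments.append(train_segments[i])
        n_sub += len(train_segments[i].beats)
        if n_sub >= schedule.apl_sample_cap:
            break
    X_sub = np.concatenate([s.feature_matrix() for s in sub_segments])

    template = None          # params object reused by the factory
    state = {"surrogate": None, "tree": None,
             "W_data": None, "apl_data": None}

    def factory(w):
        saved = template.flatten()
        template.set_flat(w)
        _, preds, _ = bilstm_core.predict_beats(sub_segments, template)
        template.set_flat(saved)
        return preds

    def penalty_fn(p: BiLSTMParams):
        if lam <= 0 or state["surrogate"] is None:
            return 0.0, None
        w = p.flatten()
        return (lam * state["surrogate"].predict(w),
                lam * state["surrogate"].grad_wrt_input(w))

    def distill_now(params: BiLSTMParams) -> dict:
        nonlocal template
        template = params
        _, preds, _ = bilstm_core.predict_beats(sub_segments, params)
        tree = distill_tree(preds, X_sub, schedule.tree_constraints,
                            seed=int(rng_treg.integers(2**31 - 1)))
        true_apl = average_path_length(tree, X_sub)
        state["tree"] = tree
        W_new, apl_new = build_surrogate_dataset(
            [params.flatten()], X_sub, factory,
            n_perturbations=schedule.n_perturbations,
            noise_sd=schedule.noise_sd, rng=rng_treg,
            constraints=schedule.tree_constraints)
        if state["W_data"] is None:
            state["W_data"], state["apl_data"] = W_new, apl_new
        else:
            state["W_data"] = np.vstack([state["W_data"], W_new])
            state["apl_data"] = np.concatenate([state["apl_data"], apl_new])
        state["surrogate"] = train_surrogate(
            state["W_data"], state["apl_data"], eps=schedule.surrogate_eps,
            hidden=schedule.surrogate_hidden, iters=schedule.surrogate_iters,
            seed=int(rng_treg.integers(2**31 - 1)))
        return {"true_apl": true_apl,
                "surrogate_apl": state["surrogate"].predict(params.flatten()),
                "fidelity": tree.fidelity,
                "surrogate_J": len(state["apl_data"])}

    def hook(epoch: int, params: BiLSTMParams):
        if epoch % schedule.distill_every == 0:
            return distill_now(params)
        return None

    params, history = bilstm_core.train_bilstm(
        train_segments, cfg, penalty_fn=penalty_fn, epoch_hook=hook)
    if cfg.epochs % schedule.distill_every != 0 or state["tree"] is None:
        final_row = distill_now(params)
        final_row["epoch"] = cfg.epochs
        history.append({"loss": history[-1]["loss"] if history else float("nan"),
                        "penalty": history[-1].get("penalty", 0.0) if history else 0.0,
                        **final_row})
    return params, state["tree"], history
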