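"""Reading the simulated decision tree: what did the network learn to use?

Three analyses on the distilled SDT:

* per-node class percentages — for every node, the share of each class's
  *total* beats that reach that node (the root therefore shows 100% for
  every class, and sibling subtrees partition their parent's share);
* feature ranking — which sample points of the 235-sample beat window the
  tree splits on, ranked by total Gini impurity decrease (split-count
  ranking available as an alternative);
* the reduced-feature experiment — retrain the classifier using only the
  top-k ranked sample points as the per-beat input and compare the
  evaluation report against the full-feature run.

Feature indices are 0-based positions within the beat window (R peak at
index 90 at 360 Hz).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from .aami import N_CLASSES, as_class
from . import bilstm_core, evaluation, tree_regularization
from .heartbeat_dataset import Beat, BeatSegment
from .tree_regularization import SimulatedDecisionTree, TregSchedule

__all__ = [
    "NodeReport",
    "node_value_percentages",
    "rank_features",
    "project_segments",
    "reduced_feature_experiment",
]


@dataclasses.dataclass(frozen=True)
class NodeReport:
    node_id: int
    is_leaf: bool
    feature: int                 # -1 for leaves
    threshold: float             # nan for leaves
    leaf_class: Optional[int]    # majority class at leaves, else None
    class_pct: np.ndarray        # (5,) percentage of each class's total beats


def node_value_percentages(tree: SimulatedDecisionTree, X, labels) -> list[NodeReport]:
    """Route every sample, tally per node, normalise by class totals x100.

    A class absent from ``labels`` gets NaN percentages (undefined-marked).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray([int(as_class(v)) for v in labels])
    if len(X) != len(y):
        raise ValueError("labels must align with X")
    counts = np.zeros((tree.n_nodes, N_CLASSES))

    def descend(node: int, idx: np.ndarray) -> None:
        counts[node] += np.bincount(y[idx], minlength=N_CLASSES)
        if tree.is_leaf(node):
            return
        left = X[idx, tree.feature[node]] <= tree.threshold[node]
        descend(tree.children_left[node], idx[left])
        descend(tree.children_right[node], idx[~left])

    descend(0, np.arange(len(X)))
    totals = counts[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * counts / totals, math.nan)

    reports = []
    for i in range(tree.n_nodes):
        leaf = tree.is_leaf(i)
        reports.append(NodeReport(
            node_id=i, is_leaf=leaf,
            feature=int(tree.feature[i]) if not leaf else -1,
            threshold=float(tree.threshold[i]) if not leaf else math.nan,
            leaf_class=int(tree.value[i].argmax()) if leaf else None,
            class_pct=pct[i],
        ))
    return reports


def _gini(v: np.ndarray) -> float:
    n = v.sum()
    if n <= 0:
        return 0.0
    p = v / n
    return float(1.0 - (p * p).sum())


def rank_features(tree: SimulatedDecisionTree, k: int,
                  mode: str = "impurity") -> list[tuple[int, float]]:
    """Top-k (feature index, weight); weights >= 0 and sum to 1 over all
    used features before truncation.  Ties break by ascending index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("impurity", "split_count"):
        raise ValueError(f"unknown ranking mode: {mode!r}")
    scores: dict[int, float] = {}
    for i in range(tree.n_nodes):
        if tree.is_leaf(i):
            continue
        f = int(tree.feature[i])
        if mode == "split_count":
            scores[f] = scores.get(f, 0.0) + 1.0
        else:
            l, r = tree.children_left[i], tree.children_right[i]
            n, nl, nr = (tree.value[i].sum(), tree.value[l].sum(),
                         tree.value[r].sum())
            dec = n * _gini(tree.value[i]) - nl * _gini(tree.value[l]) \
                - nr * _gini(tree.value[r])
            scores[f] = scores.get(f, 0.0) + max(dec, 0.0)
    total = sum(scores.values())
    if total > 0:
        scores = {f: s / total for f, s in scores.items()}
    ranked = sorted(scores.items(), key=lambda fs: (-fs[1], fs[0]))
    return ranked[:k]


def project_segments(segments: Sequence[BeatSegment],
                     feature_indices) -> list[BeatSegment]:
    """Segments whose beats keep only the selected window sample points."""
    idx = np.asarray(feature_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("feature_indices must be non-empty")
    out = []
    for seg in segments:
        beats = [Beat(samples=b.samples[idx], label=b.label,
                      r_index_in_window=b.r_index_in_window,
                      source_record=b.source_record,
                      position_in_record=b.position_in_record)
                 for b in seg.beats]
        out.append(BeatSegment(beats=beats, t=seg.t))
    return out


def _evaluate(segments, params) -> dict:
    y_true, y_pred, _ = bilstm_core.predict_beats(segments, params)
    cm = evaluation.confusion_matrix(y_true, y_pred)
    result = evaluation.metrics(cm)
    result["confusion"] = cm
    return result


def reduced_feature_experiment(train_segments, test_segments, feature_indices,
                               cfg: bilstm_core.TrainConfig,
                               schedule: TregSchedule) -> dict:
    """Retrain on the selected sample points only; report both runs.

    Returns ``{"full": report, "reduced": report}`` where each report holds
    the confusion matrix and per-class metrics on the test segments.  The
    beat window bounds are validated against the training data.
    """
    n_features = train_segments[0].beats[0].samples.size
    idx = np.asarray(feature_indices, dtype=int)
    if idx.size == 0 or idx.min() < 0 or idx.max() >= n_features:
        raise ValueError(f"feature indices must lie in 0..{n_features - 1}")

    def run(train, test):
        if cfg.regularizer == "tree":
            params, _, _ = tree_regularization.train_bilstm_treg(
                train, cfg, schedule)
        else:
            params, _ = bilstm_core.train_bilstm(train, cfg)
        return _evaluate(test, params)

    full = run(train_segments, test_segments)
    reduced = run(project_segments(train_segments, idx),
                  project_segments(test_segments, idx))
    return {"full": full, "reduced": reduced}
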