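"""Feature construction and the CART decision-tree classification protocol.

Each cell is described by a 265-dimensional feature vector:

    1   circular-form flag (1 circular, 0 non-circular)
  + 1   TPE-AF intensity normalized per mW (49-pixel binned neighborhood)
  + 256 peak-normalized decay-curve samples
  + 7   bi-exponential parameters (tau1, tau2, tau_m, a1, a2, a1/a2,
        (a1 - a2)/(a1 + a2))
  = 265

Cell size is deliberately not a feature.  The classifier is a CART tree
grown with Gini impurity H(Q) = 1 - sum_k p_k^2: at each node the split
theta = (j, t_m) minimizing

    G(Q, theta) = n_left/N_m H(Q_left) + n_right/N_m H(Q_right)

is found by exhaustive search over features and midpoints between
consecutive sorted unique values, with the inclusive-left partition
x_j <= t_m.  Ties in G are broken toward the lowest feature index, then
the lowest threshold.  Hyperparameters follow the study protocol: maximum
depth 6, minimum 2 samples to split, equal sample weights.  Evaluation
repeats a uniformly random 60/40 train/test split 1,000 times and reports
per-class sensitivity (true positive rate) and specificity (true negative
rate) as mean +- SD, plus a pooled ROC from leaf class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_LENGTH = 265
N_CURVE = 256

FLIM_FEATURE_NAMES = ["tau1", "tau2", "tau_m", "a1", "a2", "ratio", "asym"]
FEATURE_NAMES = (["shape_flag", "norm_intensity"]
                 + [f"d{k:03d}" for k in range(N_CURVE)]
                 + FLIM_FEATURE_NAMES)


def build_features(record) -> np.ndarray:
    """Assemble the 265-vector from a cell record.

    Accepts a :class:`~mcflim.cellscan.CellRecord` or any mapping/row with
    ``shape_flag``, an intensity field, ``d000``...``d255`` and the seven
    bi-exponential parameters.  Cell size is not included, so two records
    differing only in diameter map to identical vectors.
    """
    from .cellscan import CellRecord  # local import to avoid a cycle

    if isinstance(record, CellRecord):
        fs = record.fit_summary
        flim = [fs["tau1"], fs["tau2"], fs["tau_m"], fs["a1"], fs["a2"],
                fs["ratio"], fs["asym"]]
        vec = np.concatenate([[float(record.shape_flag), record.mean_intensity],
                              record.decay_curve, flim])
    else:
        intensity = record["intensity"] if "intensity" in record else record["mean_intensity"]
        curve = [record[f"d{k:03d}"] for k in range(N_CURVE)]
        flim = [record[name] for name in
                ("tau1", "tau2", "tau_m", "a1", "a2", "ratio", "asym")]
        vec = np.concatenate([[float(record["shape_flag"]), float(intensity)],
                              curve, flim])
    if vec.size != FEATURE_LENGTH:
        raise ValueError(f"feature vector has length {vec.size}, expected {FEATURE_LENGTH}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("feature vector contains non-finite entries")
    return vec


def cohort_features(cohort: pd.DataFrame, scheme: str = "binary"):
    """Feature matrix and label vector for a generated cohort table."""
    if scheme not in ("binary", "three_class"):
        raise ValueError(f"unknown label scheme {scheme!r}")
    cols = (["shape_flag", "intensity"]
            + [f"d{k:03d}" for k in range(N_CURVE)]
            + ["tau1", "tau2", "tau_m", "a1", "a2", "ratio", "asym"])
    X = cohort[cols].to_numpy(dtype=float)
    y = cohort["label2" if scheme == "binary" else "label3"].to_numpy(dtype=int)
    return X, y


def gini(labels) -> float:
    """Gini impurity 1 - sum_k p_k^2 of a label multiset."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("Gini impurity undefined for an empty set")
    _, counts = np.unique(y, return_counts=True)
    p = counts / y.size
    return float(1.0 - np.sum(p**2))


def best_split(X: np.ndarray, y: np.ndarray, n_classes: int | None = None):
    """Exhaustive Gini-optimal split; returns (feature, threshold, G) or None.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values per feature; the left branch takes x_j <= t.  Returns None when
    every feature is constant (leaf signal).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if n_classes is None:
        n_classes = int(y.max()) + 1
    if n < 2 or np.all(y == y[0]):  # pure node: leaf signal
        return None

    order = np.argsort(X, axis=0, kind="stable")  # (n, p)
    Xs = np.take_along_axis(X, order, axis=0)
    onehot = np.eye(n_classes)[y]  # (n, K)
    # class counts left of each candidate cut, per feature: (n, p, K)
    cum = np.cumsum(onehot[order], axis=0)
    left_n = np.arange(1, n, dtype=float)[:, None]  # cuts after sample i -> i+1 left
    right_n = n - left_n
    left_counts = cum[:-1]  # (n-1, p, K)
    right_counts = cum[-1][None, :, :] - left_counts
    gini_left = 1.0 - np.sum((left_counts / left_n[..., None]) ** 2, axis=2)
    gini_right = 1.0 - np.sum((right_counts / right_n[..., None]) ** 2, axis=2)
    G = (left_n * gini_left + right_n * gini_right) / n  # (n-1, p)
    valid = Xs[1:] > Xs[:-1]
    if not valid.any():
        return None
    G = np.where(valid, G, np.inf)
    # lowest feature index first, then lowest threshold: scan feature-major
    flat = np.argmin(G.T)  # row-major over (p, n-1)
    j, i = divmod(int(flat), n - 1)
    thr = 0.5 * (Xs[i, j] + Xs[i + 1, j])
    return j, float(thr), float(G[i, j])


@dataclass
class DecisionTree:
    """CART tree in flat-array form; leaves store class-proportion rows p_mk."""

    feature: np.ndarray  # (n_nodes,), -1 for leaves
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    proba: np.ndarray  # (n_nodes, K)
    n_classes: int
    max_depth: int = 6

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    def depth(self) -> int:
        def _d(node):
            if self.feature[node] < 0:
                return 0
            return 1 + max(_d(self.left[node]), _d(self.right[node]))
        return _d(0)


def grow_tree(X: np.ndarray, y: np.ndarray, max_depth: int = 6,
              min_samples_split: int = 2, n_classes: int | None = None) -> DecisionTree:
    """Grow a CART tree by recursive Gini-optimal splitting.

    Recursion stops at purity, fewer than ``min_samples_split`` samples,
    ``max_depth``, or when no informative split exists.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size or y.size == 0:
        raise ValueError("X must be (n, p) with matching non-empty labels")
    if n_classes is None:
        n_classes = int(y.max()) + 1

    feature, threshold, left, right, proba = [], [], [], [], []

    def new_node(idx):
        node = len(feature)
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        counts = np.bincount(y[idx], minlength=n_classes)
        proba.append(counts / idx.size)
        return node

    def build(idx, depth):
        node = new_node(idx)
        yi = y[idx]
        if (depth >= max_depth or idx.size < min_samples_split
                or np.all(yi == yi[0])):
            return node
        split = best_split(X[idx], yi, n_classes)
        if split is None:
            return node
        j, thr, _ = split
        go_left = X[idx, j] <= thr
        feature[node] = j
        threshold[node] = thr
        left_child = build(idx[go_left], depth + 1)
        right_child = build(idx[~go_left], depth + 1)
        left[node] = left_child
        right[node] = right_child
        return node

    build(np.arange(y.size), 0)
    return DecisionTree(np.asarray(feature), np.asarray(threshold),
                        np.asarray(left), np.asarray(right),
                        np.asarray(proba), n_classes, max_depth)


def predict(tree: DecisionTree, X: np.ndarray):
    """Predicted class (argmax p_mk, ties to the lowest class index) and p_mk rows.

    Routing uses the inclusive-left rule: x_j <= t_m goes left.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    n = X.shape[0]
    node = np.zeros(n, dtype=int)
    while True:
        rows = np.nonzero(tree.feature[node] >= 0)[0]
        if rows.size == 0:
            break
        cur = node[rows]
        go_left = X[rows, tree.feature[cur]] <= tree.threshold[cur]
        node[rows] = np.where(go_left, tree.left[cur], tree.right[cur])
    out = tree.proba[node]
    labels = np.argmax(out, axis=1)  # argmax takes the lowest index on ties
    return labels, out


@dataclass
class ClassifierReport:
    """Sensitivity/specificity (mean +- SD over repeats) and pooled ROC points."""

    scheme: str
    n_repeats: int
    test_fraction: float
    base_seed: int
    class_labels: list
    sensitivity_mean: dict
    sensitivity_sd: dict
    specificity_mean: dict
    specificity_sd: dict
    skipped_repeats: dict
    confusion_total: np.ndarray
    roc: dict = field(default_factory=dict)  # class -> (fpr, tpr) arrays

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_repeats": self.n_repeats,
            "test_fraction": self.test_fraction,
            "base_seed": self.base_seed,
            "class_labels": list(self.class_labels),
            "sensitivity_mean": {str(k): v for k, v in self.sensitivity_mean.items()},
            "sensitivity_sd": {str(k): v for k, v in self.sensitivity_sd.items()},
            "specificity_mean": {str(k): v for k, v in self.specificity_mean.items()},
            "specificity_sd": {str(k): v for k, v in self.specificity_sd.items()},
            "skipped_repeats": {str(k): v for k, v in self.skipped_repeats.items()},
            "confusion_total": self.confusion_total.tolist(),
        }


def roc_points(scores: np.ndarray, positive: np.ndarray):
    """ROC curve (FPR, TPR) swept over all score thresholds."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(positive[order])
    fp = np.cumsum(~positive[order])
    # collapse tied scores to one operating point
    distinct = np.r_[np.nonzero(np.diff(scores[order]))[0], scores.size - 1]
    tpr = np.r_[0.0, tp[distinct] / max(positive.sum(), 1)]
    fpr = np.r_[0.0, fp[distinct] / max((~positive).sum(), 1)]
    return fpr, tpr


def evaluate(X: np.ndarray, y: np.ndarray, scheme: str = "binary",
             n_repeats: int = 1000, test_fraction: float = 0.4,
             base_seed: int = 0, max_depth: int = 6,
             min_samples_split: int = 2) -> ClassifierReport:
    """Repeated randomized 60/40 train/test evaluation of the CART tree.

    Each repeat draws a fresh uniform (unstratified) split with seed
    ``base_seed + repeat``, fits a tree on the training part and scores the
    test part.  Per-class sensitivity is the one-vs-rest true positive rate,
    specificity the true negative rate; repeats whose test set lacks a class
    skip that class's rates (counted in the report).  Leaf probabilities are
    pooled across repeats into per-class ROC curves.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("evaluation needs at least two classes")
    K = int(classes.max()) + 1
    n = y.size
    n_test = int(round(test_fraction * n))

    sens = {int(k): [] for k in classes}
    spec = {int(k): [] for k in classes}
    skipped = {int(k): 0 for k in classes}
    confusion_total = np.zeros((K, K), dtype=int)
    pooled_scores = {int(k): [] for k in classes}
    pooled_truth = {int(k): [] for k in classes}

    for rep in range(n_repeats):
        rng = np.random.default_rng(base_seed + rep)
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        tree = grow_tree(X[train_idx], y[train_idx], max_depth=max_depth,
                         min_samples_split=min_samples_split, n_classes=K)
        pred, proba = predict(tree, X[test_idx])
        yt = y[test_idx]
        C = np.zeros((K, K), dtype=int)
        np.add.at(C, (yt, pred), 1)
        confusion_total += C
        total = C.sum()
        for k in classes:
            k = int(k)
            pos = C[k].sum()
            if pos == 0:
                skipped[k] += 1
            else:
                sens[k].append(C[k, k] / pos)
            neg = total - pos
            if neg > 0:
                fp = C[:, k].sum() - C[k, k]
                spec[k].append((neg - fp) / neg)
            pooled_scores[k].append(proba[:, k])
            pooled_truth[k].append(yt == k)

    roc = {}
    for k in classes:
        k = int(k)
        roc[k] = roc_points(np.concatenate(pooled_scores[k]),
                            np.concatenate(pooled_truth[k]))

    return ClassifierReport(
        scheme=scheme, n_repeats=n_repeats, test_fraction=test_fraction,
        base_seed=base_seed, class_labels=[int(k) for k in classes],
        sensitivity_mean={k: float(np.mean(v)) for k, v in sens.items()},
        sensitivity_sd={k: float(np.std(v)) for k, v in sens.items()},
        specificity_mean={k: float(np.mean(v)) for k, v in spec.items()},
        specificity_sd={k: float(np.std(v)) for k, v in spec.items()},
        skipped_repeats=skipped, confusion_total=confusion_total, roc=roc,
    )


def evaluate_cohort(cohort: pd.DataFrame, scheme: str = "binary", **kwargs) -> ClassifierReport:
    """Convenience wrapper: features + labels from a cohort table, then evaluate."""
    X, y = cohort_features(cohort, scheme)
    return evaluate(X, y, scheme=scheme, **kwargs)
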