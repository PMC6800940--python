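"""Bagged CART decision forest with out-of-bag estimation, from scratch.

Trees are grown on bootstrap samples (m draws with replacement from m
training rows) by recursive binary splitting.  Node impurity is the Gini
value 1 - sum_k p_k^2; a split's quality is the size-weighted mean impurity
of its children, and the accepted split is the (feature, threshold) pair
minimizing it over all midpoints of consecutive distinct sorted feature
values.  Growth stops at purity, below min_samples_split, or when no split
leaves both children with min_samples_leaf rows; leaves predict their
majority class with ties going to the negative (non-PVC) class.  There is no
pruning.

The ensemble predicts by majority vote over trees (vote ties again fall to
non-PVC).  Because each tree records its in-bag multiset, the forest can
score itself on the training set out of bag: a row is voted on only by trees
whose bootstrap missed it, and the OOB error is the misclassified fraction
among rows covered by at least one such tree.

Determinism: a single seeded generator drives bootstrap draws and the
per-split feature subsampling, so a fixed seed reproduces the forest bit for
bit.  Split ties break toward the lowest feature index, then the lowest
threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TreeNode", "ForestParams", "Forest", "OOBResult",
    "gini", "gini_index", "best_split", "grow_tree", "fit",
    "predict", "predict_proba", "oob_predictions", "oob_error",
    "single_feature_importance", "forest_to_json", "forest_from_json",
    "save_forest", "load_forest",
]


def gini(counts: Sequence[float] | np.ndarray) -> float:
    """Gini impurity 1 - sum p_k^2 of a class-count vector.

    0 for a pure set; 1/2 for two equally frequent classes.
    """
    c = np.asarray(counts, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("class counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot compute Gini of an empty set")
    p = c / total
    return float(1.0 - np.sum(p * p))


def gini_index(y: np.ndarray, parts: Sequence[np.ndarray]) -> float:
    """Size-weighted Gini impurity of a disjoint partition of the label set.

    ``parts`` are index arrays into ``y`` covering it disjointly; empty parts
    carry zero weight.
    """
    y = np.asarray(y)
    n = sum(len(p) for p in parts)
    if n != y.size:
        raise ValueError("partition does not cover the label set")
    total = 0.0
    for p in parts:
        if len(p) == 0:
            continue
        labels = y[np.asarray(p)]
        counts = np.bincount(labels.astype(np.int64), minlength=2)
        total += (len(p) / n) * gini(counts)
    return total


@dataclass
class TreeNode:
    """Internal node (feature, threshold, children) or leaf (counts, prediction)."""

    feature: int = -1
    threshold: float = float("nan")
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    counts: np.ndarray | None = None
    prediction: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class ForestParams:
    n_estimators: int = 120
    min_samples_split: int = 100
    min_samples_leaf: int = 30
    features_per_split: str = "sqrt"   # "sqrt" or "all" (pure bagging)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.features_per_split not in {"sqrt", "all"}:
            raise ValueError("features_per_split must be 'sqrt' or 'all'")
        if self.min_samples_leaf < 1 or self.min_samples_split < 2:
            raise ValueError("min_samples_leaf >= 1 and min_samples_split >= 2 required")


@dataclass
class Forest:
    trees: list[TreeNode]
    inbag: list[np.ndarray]        # per-tree bootstrap index multisets (m draws each)
    params: ForestParams
    n_features: int
    m: int = 0                     # training-set size

    def __post_init__(self) -> None:
        if self.m == 0 and self.inbag:
            self.m = len(self.inbag[0])


def best_split(X: np.ndarray, y: np.ndarray,
               feature_indices: Sequence[int] | None = None,
               min_samples_leaf: int = 1) -> tuple[int, float, float] | None:
    """Exhaustive binary-threshold search minimizing the weighted child Gini.

    Candidate thresholds are midpoints of consecutive distinct sorted values
    per feature; both children must keep at least ``min_samples_leaf`` rows.
    Returns (feature, threshold, gain) with gain = parent impurity minus the
    weighted child impurity, or None when no valid split exists.  Ties break
    toward the lowest feature index, then the lowest threshold.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    feats = sorted(feature_indices) if feature_indices is not None else range(X.shape[1])
    parent = gini(np.bincount(y, minlength=2))
    if parent == 0.0:
        return None                                     # pure set: nothing to gain
    best: tuple[int, float, float] | None = None
    best_score = np.inf
    for f in feats:
        v = X[:, f]
        order = np.argsort(v, kind="stable")
        vs, ys = v[order], y[order]
        cum1 = np.cumsum(ys)
        total1 = cum1[-1]
        sizes_l = np.arange(1, n)                       # left size at split position
        valid = (vs[1:] > vs[:-1]) & (sizes_l >= min_samples_leaf) \
            & ((n - sizes_l) >= min_samples_leaf)
        if not np.any(valid):
            continue
        pos = np.nonzero(valid)[0] + 1
        n_l = pos.astype(np.float64)
        n_r = n - n_l
        l1 = cum1[pos - 1].astype(np.float64)
        l0 = n_l - l1
        r1 = total1 - l1
        r0 = n_r - r1
        g_l = 1.0 - (l1 / n_l) ** 2 - (l0 / n_l) ** 2
        g_r = 1.0 - (r1 / n_r) ** 2 - (r0 / n_r) ** 2
        weighted = (n_l / n) * g_l + (n_r / n) * g_r
        k = int(np.argmin(weighted))                    # first min => lowest threshold
        if weighted[k] < best_score:
            thr = 0.5 * (vs[pos[k] - 1] + vs[pos[k]])
            best_score = float(weighted[k])
            best = (int(f), float(thr), float(parent - weighted[k]))
    return best


def _leaf(y: np.ndarray) -> TreeNode:
    counts = np.bincount(y, minlength=2)
    # majority prediction; ties fall to class 0 (non-PVC)
    pred = int(counts[1] > counts[0])
    return TreeNode(counts=counts, prediction=pred)


def grow_tree(X: np.ndarray, y: np.ndarray, params: ForestParams,
              rng: np.random.Generator | None = None) -> TreeNode:
    """Grow one CART tree to the stopping rules (no pruning)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if y.size == 0:
        raise ValueError("cannot grow a tree on an empty set")
    rng = rng or np.random.default_rng(params.seed)
    nf = X.shape[1]
    k = max(int(np.ceil(np.sqrt(nf))), 1) if params.features_per_split == "sqrt" else nf

    def build(idx: np.ndarray) -> TreeNode:
        ys = y[idx]
        if ys.size < params.min_samples_split or np.all(ys == ys[0]):
            return _leaf(ys)
        feats = np.sort(rng.choice(nf, size=k, replace=False)) if k < nf else None
        found = best_split(X[idx], ys, feats, params.min_samples_leaf)
        if found is None:
            return _leaf(ys)
        f, thr, _gain = found
        mask = X[idx, f] <= thr
        node = TreeNode(feature=f, threshold=thr, counts=np.bincount(ys, minlength=2))
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    return build(np.arange(y.size))


def fit(X: np.ndarray, y: np.ndarray, params: ForestParams | None = None) -> Forest:
    """Train a bagged forest: T trees, each on an m-draw bootstrap of (X, y)."""
    params = params or ForestParams()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    m = y.size
    rng = np.random.default_rng(params.seed)
    trees, inbag = [], []
    for _ in range(params.n_estimators):
        boot = rng.integers(0, m, size=m)
        trees.append(grow_tree(X[boot], y[boot], params, rng))
        inbag.append(boot)
    return Forest(trees=trees, inbag=inbag, params=params, n_features=X.shape[1], m=m)


def _apply_tree(node: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=np.int64)

    def walk(nd: TreeNode, idx: np.ndarray) -> None:
        if nd.is_leaf:
            out[idx] = nd.prediction
            return
        mask = X[idx, nd.feature] <= nd.threshold
        walk(nd.left, idx[mask])
        walk(nd.right, idx[~mask])

    walk(node, np.arange(X.shape[0]))
    return out


def _check_dim(forest: Forest, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != forest.n_features:
        raise ValueError(f"expected {forest.n_features} features, got {X.shape[1]}")
    return X


def predict_proba(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting PVC for each row."""
    X = _check_dim(forest, X)
    votes = np.zeros(X.shape[0], dtype=np.float64)
    for t in forest.trees:
        votes += _apply_tree(t, X)
    return votes / len(forest.trees)


def predict(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Majority-vote label per row (vote ties -> non-PVC)."""
    return (predict_proba(forest, X) > 0.5).astype(np.int64)


@dataclass
class OOBResult:
    error: float
    n_evaluated: int      # rows with at least one out-of-bag tree
    n_uncovered: int      # rows every tree saw in-bag (excluded)


def oob_predictions(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Out-of-bag label per training row; -1 where no tree left the row out."""
    X = _check_dim(forest, X)
    m = X.shape[0]
    votes = np.zeros((m, 2), dtype=np.int64)
    for tree, boot in zip(forest.trees, forest.inbag):
        oob = np.ones(m, dtype=bool)
        oob[np.unique(boot)] = False
        if not np.any(oob):
            continue
        pred = _apply_tree(tree, X[oob])
        votes[np.nonzero(oob)[0], pred] += 1
    covered = votes.sum(axis=1) > 0
    out = np.full(m, -1, dtype=np.int64)
    out[covered] = (votes[covered, 1] > votes[covered, 0]).astype(np.int64)
    return out


def oob_error(forest: Forest, X: np.ndarray, y: np.ndarray) -> OOBResult:
    """Out-of-bag estimate of the generalization error on the training set."""
    y = np.asarray(y, dtype=np.int64)
    pred = oob_predictions(forest, X)
    covered = pred >= 0
    n_cov = int(covered.sum())
    err = float(np.mean(pred[covered] != y[covered])) if n_cov else float("nan")
    return OOBResult(error=err, n_evaluated=n_cov, n_uncovered=int(y.size - n_cov))


def single_feature_importance(X_train: np.ndarray, y_train: np.ndarray,
                              X_eval: np.ndarray, y_eval: np.ndarray,
                              params: ForestParams | None = None,
                              feature_names: Sequence[str] | None = None,
                              ) -> list[dict[str, object]]:
    """Rank features by how many PVC beats each identifies on its own.

    For every feature, a forest is trained on that single column and the
    correctly identified PVC beats on the evaluation set are counted.
    Returns one record per feature, sorted by descending count (rank 1 =
    most discriminative; count ties keep feature order).
    """
    params = params or ForestParams()
    X_train = np.asarray(X_train, dtype=np.float64)
    X_eval = np.asarray(X_eval, dtype=np.float64)
    y_eval = np.asarray(y_eval, dtype=np.int64)
    nf = X_train.shape[1]
    if nf < 2:
        raise ValueError("importance ranking needs at least 2 features")
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(nf)]
    records = []
    for f in range(nf):
        forest_f = fit(X_train[:, [f]], y_train, params)
        pred = predict(forest_f, X_eval[:, [f]])
        correct_v = int(np.sum((y_eval == 1) & (pred == 1)))
        records.append({"feature": names[f], "correct_pvc": correct_v})
    order = sorted(range(nf), key=lambda i: -records[i]["correct_pvc"])
    for rank, i in enumerate(order, start=1):
        records[i]["rank"] = rank
    return sorted(records, key=lambda r: r["rank"])


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"counts": [int(c) for c in node.counts], "prediction": node.prediction}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "counts": None if node.counts is None else [int(c) for c in node.counts],
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if "feature" not in d:
        return TreeNode(counts=np.asarray(d["counts"]), prediction=int(d["prediction"]))
    return TreeNode(
        feature=int(d["feature"]), threshold=float(d["threshold"]),
        counts=None if d.get("counts") is None else np.asarray(d["counts"]),
        left=_node_from_dict(d["left"]), right=_node_from_dict(d["right"]),
    )


def forest_to_json(forest: Forest) -> str:
    payload = {
        "params": {
            "n_estimators": forest.params.n_estimators,
            "min_samples_split": forest.params.min_samples_split,
            "min_samples_leaf": forest.params.min_samples_leaf,
            "features_per_split": forest.params.features_per_split,
            "seed": forest.params.seed,
        },
        "n_features": forest.n_features,
        "m": forest.m,
        "inbag": [b.tolist() for b in forest.inbag],
        "trees": [_node_to_dict(t) for t in forest.trees],
    }
    return json.dumps(payload)


def forest_from_json(text: str) -> Forest:
    d = json.loads(text)
    params = ForestParams(**d["params"])
    return Forest(
        trees=[_node_from_dict(t) for t in d["trees"]],
        inbag=[np.asarray(b, dtype=np.int64) for b in d["inbag"]],
        params=params, n_features=int(d["n_features"]), m=int(d["m"]),
    )


def save_forest(forest: Forest, path: str | Path) -> None:
    Path(path).write_text(forest_to_json(forest))


def load_forest(path: str | Path) -> Forest:
    return forest_from_json(Path(path).read_text())
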