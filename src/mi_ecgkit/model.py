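"""Second-order gradient-boosted decision trees (softmax multiclass).

The booster minimizes regularized softmax cross-entropy by Newton boosting:
each round, per-sample gradients g_i = p_i - 1{true class} and Hessians
h_i = p_i (1 - p_i) are computed from the current scores, and one
regression tree per class is grown greedily.  With node sums
G = sum g_i, H = sum h_i, the optimal leaf weight is

    w* = -G / (H + lambda)

and a split's gain is

    1/2 [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda) - G^2/(H+lambda) ] - gamma

where lambda is the L2 penalty on leaf weights and gamma the per-leaf
penalty.  Split finding is an exact greedy scan over sorted feature
values; ties are broken toward the lowest feature index, then the lowest
threshold.  Column subsampling per tree is supported and seeded.

This module is self-contained on purpose: the split/leaf algebra above is
the method under study.  An external boosted-tree library is used in the
test-suite only, as an independent comparator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

_EPS_GAIN = 1e-12


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_grad_hess(scores: np.ndarray, y_index: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample, per-class first and second derivatives of the softmax
    cross-entropy loss: g = p - 1{class}, h = p(1-p).  h >= 0 always.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    p = softmax(scores)
    g = p.copy()
    g[np.arange(len(y_index)), y_index] -= 1.0
    h = p * (1.0 - p)
    return g, h


def leaf_weight(G: float, H: float, lam: float) -> float:
    """Optimal leaf weight w* = -G/(H + lambda)."""
    denom = H + lam
    if denom <= 0:
        raise ValueError("H + lambda must be positive")
    return -G / denom


def best_split(X: np.ndarray, g: np.ndarray, h: np.ndarray,
               reg_lambda: float = 1.0, gamma: float = 0.0):
    """Exact greedy best split of one node.

    Returns ``(feature, threshold, gain)`` or ``None`` when no split has
    positive gain.  Thresholds are midpoints between consecutive distinct
    sorted values.  Ties: lowest feature index, then lowest threshold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty node")
    Xt = np.ascontiguousarray(X.T)
    order = np.argsort(Xt, axis=1, kind="stable")
    found = _scan_node(Xt, order, np.asarray(g, float), np.asarray(h, float),
                       reg_lambda, gamma)
    if found is None:
        return None
    feat, pos, gain, thr = found
    return int(feat), float(thr), float(gain)


def _scan_node(Xt: np.ndarray, order: np.ndarray, g: np.ndarray,
               h: np.ndarray, lam: float, gamma: float):
    """Vectorized gain scan.  ``Xt`` is feature-major (d x n_total) and
    ``order`` (d x n_node) holds per-feature sorted sample indices."""
    d, n = order.shape
    if n < 2:
        return None
    xs = np.take_along_axis(Xt, order, axis=1)        # sorted values, d x n
    gl = np.cumsum(g[order], axis=1)[:, :-1]          # left sums, d x (n-1)
    hl = np.cumsum(h[order], axis=1)[:, :-1]
    node_idx = order[0]                               # node membership
    G, H = g[node_idx].sum(), h[node_idx].sum()
    parent = G * G / (H + lam)
    # gains computed with in-place ops to limit temporary traffic
    gr = G - gl
    np.multiply(gr, gr, out=gr)
    hr = (H + lam) - hl
    np.divide(gr, hr, out=gr)                         # GR^2/(HR+lam)
    np.multiply(gl, gl, out=gl)
    hl += lam
    np.divide(gl, hl, out=gl)                         # GL^2/(HL+lam)
    gains = gl
    gains += gr
    gains -= parent
    gains *= 0.5
    gains -= gamma
    gains[xs[:, 1:] == xs[:, :-1]] = -np.inf          # no split between ties
    # row-major argmax -> lowest feature index, then lowest threshold
    flat = np.argmax(gains)
    feat, pos = divmod(flat, n - 1)
    gain = gains[feat, pos]
    if not np.isfinite(gain) or gain <= _EPS_GAIN:
        return None
    thr = 0.5 * (xs[feat, pos] + xs[feat, pos + 1])
    return feat, pos, gain, thr


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    weight: float = 0.0
    G: float = 0.0
    H: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"weight": self.weight, "G": self.G, "H": self.H}
        return {"feature": self.feature, "threshold": self.threshold,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @staticmethod
    def from_dict(d: dict) -> "_Node":
        if "feature" not in d:
            return _Node(weight=d["weight"], G=d.get("G", 0.0),
                         H=d.get("H", 0.0))
        return _Node(feature=d["feature"], threshold=d["threshold"],
                     left=_Node.from_dict(d["left"]),
                     right=_Node.from_dict(d["right"]))


class _Tree:
    """One regression tree grown on (g, h) with exact greedy splits."""

    def __init__(self, max_depth: int, reg_lambda: float, gamma: float,
                 columns: np.ndarray):
        self.max_depth = max_depth
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.columns = columns          # global feature indices used
        self.root: _Node | None = None

    def fit(self, Xs: np.ndarray, g: np.ndarray, h: np.ndarray,
            root_order: np.ndarray | None = None) -> "_Tree":
        Xt = np.ascontiguousarray(Xs.T)                # feature-major
        if root_order is None:
            root_order = np.argsort(Xt, axis=1, kind="stable")
        self.root = self._grow(Xt, root_order, g, h, depth=0)
        return self

    def _grow(self, Xt, order, g, h, depth) -> _Node:
        node_idx = order[0]
        G, H = float(g[node_idx].sum()), float(h[node_idx].sum())
        node = _Node(G=G, H=H,
                     weight=leaf_weight(G, H, self.reg_lambda))
        if depth >= self.max_depth or order.shape[1] < 2:
            return node
        found = _scan_node(Xt, order, g, h, self.reg_lambda, self.gamma)
        if found is None:
            return node
        feat, pos, gain, thr = found
        left_mask = np.zeros(Xt.shape[1], dtype=bool)
        left_mask[order[feat, :pos + 1]] = True
        # children keep their parent's sort orders, filtered (stable)
        sel = left_mask[order]                         # d x n bool
        n_left = pos + 1
        left_order = order[sel].reshape(Xt.shape[0], n_left)
        right_order = order[~sel].reshape(Xt.shape[0],
                                          order.shape[1] - n_left)
        node.feature = int(feat)
        node.threshold = float(thr)
        node.left = self._grow(Xt, left_order, g, h, depth + 1)
        node.right = self._grow(Xt, right_order, g, h, depth + 1)
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        stack = [(self.root, np.arange(X.shape[0]))]
        Xs = X[:, self.columns]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if node.is_leaf:
                out[idx] = node.weight
                continue
            go_left = Xs[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return out


class GradientBoostedTreeClassifier(BaseEstimator, ClassifierMixin):
    """Softmax Newton-boosted trees with exact greedy split finding.

    Parameters
    ----------
    n_estimators : boosting rounds (one tree per class per round).
    learning_rate : shrinkage applied to each tree's leaf weights.
    max_depth : maximum tree depth.
    reg_lambda : L2 penalty on leaf weights (lambda).
    gamma : per-leaf penalty; a split must beat it to be accepted.
    colsample : fraction of features drawn (without replacement, seeded)
        per tree.
    random_state : seed for column subsampling.

    Attributes (after fit)
    ----------------------
    classes_ : class labels in training order.
    trees_ : list of per-round lists of fitted trees (one per class).
    train_loss_ : per-round training log-loss (non-increasing for
        reasonable learning rates).
    """

    def __init__(self, n_estimators: int = 200, learning_rate: float = 0.1,
                 max_depth: int = 6, reg_lambda: float = 1.0,
                 gamma: float = 0.0, colsample: float = 0.8,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.colsample = colsample
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.isnan(X).any():
            raise ValueError("missing values are not supported")
        self.classes_, y_index = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        n, d = X.shape
        K = self.classes_.size
        rng = np.random.default_rng(self.random_state)
        n_cols = max(1, int(round(self.colsample * d)))
        F = np.zeros((n, K))
        # feature-major presort, shared across every tree of the fit
        presort = np.argsort(np.ascontiguousarray(X.T), axis=1,
                             kind="stable").astype(np.int32)
        self.trees_: list[list[_Tree]] = []
        self.train_loss_: list[float] = []
        for _ in range(self.n_estimators):
            g, h = softmax_grad_hess(F, y_index)
            round_trees = []
            for k in range(K):
                cols = (np.sort(rng.choice(d, size=n_cols, replace=False))
                        if n_cols < d else np.arange(d))
                tree = _Tree(self.max_depth, self.reg_lambda, self.gamma,
                             cols).fit(X[:, cols], g[:, k], h[:, k],
                                       root_order=presort[cols])
                F[:, k] += self.learning_rate * tree.predict(X)
                round_trees.append(tree)
            self.trees_.append(round_trees)
            p = softmax(F)
            self.train_loss_.append(float(
                -np.mean(np.log(p[np.arange(n), y_index] + 1e-300))))
        self.n_features_in_ = d
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        F = np.zeros((X.shape[0], self.classes_.size))
        for round_trees in self.trees_:
            for k, tree in enumerate(round_trees):
                F[:, k] += self.learning_rate * tree.predict(X)
        return F

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- JSON serialization -------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "trees_")
        payload = {
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "n_features": self.n_features_in_,
            "trees": [[{"columns": t.columns.tolist(),
                        "root": t.root.to_dict()}
                       for t in rnd] for rnd in self.trees_],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GradientBoostedTreeClassifier":
        payload = json.loads(text)
        model = cls(**payload["params"])
        model.classes_ = np.asarray(payload["classes"])
        model.n_features_in_ = payload["n_features"]
        model.trees_ = []
        for rnd in payload["trees"]:
            round_trees = []
            for td in rnd:
                t = _Tree(model.max_depth, model.reg_lambda, model.gamma,
                          np.asarray(td["columns"], dtype=int))
                t.root = _Node.from_dict(td["root"])
                round_trees.append(t)
            model.trees_.append(round_trees)
        model.train_loss_ = []
        return model

    def total_leaves(self) -> int:
        check_is_fitted(self, "trees_")
        return sum(t.root.n_leaves() for rnd in self.trees_ for t in rnd)
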