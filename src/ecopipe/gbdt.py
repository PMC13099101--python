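"""Newton-boosted regression trees for binary classification.

A from-scratch additive tree ensemble in the regularized gradient-boosting
family: each round fits a regression tree to the first- and second-order
derivatives (g, h) of the logistic loss at the current margin, leaf weights
are the Newton step ``w = -G / (H + lambda)``, and split gain is

    0.5 * [G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda) - G^2/(H+lambda)] - gamma

so the complexity penalty ``gamma*T + 0.5*lambda*sum w^2`` is honoured.
Predictions accumulate ``base_margin + eta * sum_t f_t(x)`` and pass
through a sigmoid.  Split search is exact greedy over midpoints of sorted
unique feature values; gain ties break to the lowest feature index, then
the lowest threshold, so training is fully deterministic given the seed
used for row/column subsampling.

Model selection uses stratified k-fold cross-validated grid search on the
macro-averaged F1 score; evaluation reports AUC (rank statistic with tie
averaging), accuracy and per-class/overall F1.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "TrainConfig",
    "GBDTModel",
    "fit_gbdt",
    "predict_proba",
    "predict_margin",
    "grid_search_cv",
    "evaluate_classifier",
    "make_pair_labels",
    "stratified_kfold",
    "f1_scores",
]


@dataclass(frozen=True)
class TrainConfig:
    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    reg_lambda: float = 1.0
    reg_gamma: float = 0.0
    min_child_weight: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.subsample <= 1 and 0 < self.colsample_bytree <= 1):
            raise ValueError("subsample and colsample_bytree must lie in (0, 1]")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.n_estimators < 0 or self.learning_rate <= 0:
            raise ValueError("invalid boosting parameters")


@dataclass
class _TreeNode:
    feature: int = -1  # -1 marks a leaf
    threshold: float = 0.0
    left: int = -1
    right: int = -1
    value: float = 0.0  # leaf weight (raw Newton step, eta applied outside)


@dataclass
class Tree:
    """Array-of-nodes tree; feature == -1 marks a leaf."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    @classmethod
    def from_nodes(cls, nodes: list) -> "Tree":
        return cls(
            feature=np.array([nd.feature for nd in nodes], dtype=np.int64),
            threshold=np.array([nd.threshold for nd in nodes], dtype=float),
            left=np.array([nd.left for nd in nodes], dtype=np.int64),
            right=np.array([nd.right for nd in nodes], dtype=np.int64),
            value=np.array([nd.value for nd in nodes], dtype=float),
        )

    def node_list(self) -> list:
        return [
            _TreeNode(
                feature=int(self.feature[i]),
                threshold=float(self.threshold[i]),
                left=int(self.left[i]),
                right=int(self.right[i]),
                value=float(self.value[i]),
            )
            for i in range(len(self.feature))
        ]

    def leaf_values(self) -> np.ndarray:
        return self.value[self.feature < 0]

    def used_features(self) -> set:
        return set(self.feature[self.feature >= 0].tolist())

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(len(X), dtype=np.int64)
        while True:
            f = self.feature[idx]
            rows = np.flatnonzero(f >= 0)
            if rows.size == 0:
                break
            nd = idx[rows]
            go_left = X[rows, f[rows]] < self.threshold[nd]
            idx[rows] = np.where(go_left, self.left[nd], self.right[nd])
        return self.value[idx]


@dataclass
class GBDTModel:
    config: TrainConfig
    trees: list = field(default_factory=list)
    base_margin: float = 0.0
    n_features: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": asdict(self.config),
                "base_margin": self.base_margin,
                "n_features": self.n_features,
                "trees": [[asdict(nd) for nd in t.node_list()] for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GBDTModel":
        d = json.loads(text)
        model = cls(
            config=TrainConfig(**d["config"]),
            base_margin=d["base_margin"],
            n_features=d["n_features"],
        )
        model.trees = [Tree.from_nodes([_TreeNode(**nd) for nd in t]) for t in d["trees"]]
        return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def _best_split(Xcol, g, h, lam, min_child_weight):
    """Best threshold for one feature: (gain_term, threshold) or None.

    gain_term is the pre-gamma structure-score improvement; thresholds are
    midpoints between consecutive distinct sorted values."""
    order = np.argsort(Xcol, kind="stable")
    xs, gs, hs = Xcol[order], g[order], h[order]
    G, H = gs.sum(), hs.sum()
    gl = np.cumsum(gs)[:-1]
    hl = np.cumsum(hs)[:-1]
    valid = xs[1:] != xs[:-1]
    if min_child_weight > 0:
        valid &= (hl >= min_child_weight) & ((H - hl) >= min_child_weight)
    if not valid.any():
        return None
    score = gl**2 / (hl + lam) + (G - gl) ** 2 / (H - hl + lam) - G**2 / (H + lam)
    score = np.where(valid, score, -np.inf)
    best = int(np.argmax(score))  # argmax takes the first (lowest threshold) on ties
    thr = 0.5 * (xs[best] + xs[best + 1])
    return 0.5 * float(score[best]), float(thr)


def _build_tree(X, g, h, cfg: TrainConfig, feat_ids) -> Tree:
    nodes: list = []

    def grow(rows: np.ndarray, depth: int) -> int:
        G, H = g[rows].sum(), h[rows].sum()
        leaf_value = -G / (H + cfg.reg_lambda)
        node_id = len(nodes)
        nodes.append(_TreeNode(value=float(leaf_value)))
        if depth >= cfg.max_depth or rows.size < 2:
            return node_id
        best = None
        for j in feat_ids:
            res = _best_split(X[rows, j], g[rows], h[rows], cfg.reg_lambda,
                              cfg.min_child_weight)
            if res is None:
                continue
            gain = res[0] - cfg.reg_gamma
            # ties -> lowest feature index then lowest threshold: strict >
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-15):
                best = (gain, j, res[1])
        if best is None:
            return node_id
        _, j, thr = best
        go_left = X[rows, j] < thr
        left_id = grow(rows[go_left], depth + 1)
        right_id = grow(rows[~go_left], depth + 1)
        nodes[node_id] = _TreeNode(feature=int(j), threshold=thr, left=left_id,
                                   right=right_id, value=0.0)
        return node_id

    grow(np.arange(len(X)), 0)
    return Tree.from_nodes(nodes)


def fit_gbdt(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None) -> GBDTModel:
    """Train the boosted ensemble on binary labels with logistic loss."""
    import warnings

    config = config or TrainConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    n, m = X.shape
    model = GBDTModel(config=config, base_margin=0.0, n_features=m)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: returning a constant model")
        p = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
        model.base_margin = math.log(p / (1 - p))
        return model
    rng = np.random.default_rng(config.seed)
    margin = np.full(n, model.base_margin)
    for _ in range(config.n_estimators):
        p = _sigmoid(margin)
        g = p - y
        h = p * (1.0 - p)
        if config.subsample < 1.0:
            rows = np.sort(
                rng.choice(n, size=max(1, int(round(config.subsample * n))), replace=False)
            )
        else:
            rows = np.arange(n)
        if config.colsample_bytree < 1.0:
            k = max(1, int(round(config.colsample_bytree * m)))
            feat_ids = np.sort(rng.choice(m, size=k, replace=False))
        else:
            feat_ids = np.arange(m)
        tree = _build_tree(X[rows], g[rows], h[rows], config, feat_ids)
        model.trees.append(tree)
        margin = margin + config.learning_rate * tree.predict(X)
    return model


def predict_margin(model: GBDTModel, X: np.ndarray) -> np.ndarray:
    """Accumulated log-odds margin: base + eta * sum of tree outputs."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    margin = np.full(len(X), model.base_margin, dtype=float)
    for tree in model.trees:
        margin += model.config.learning_rate * tree.predict(X)
    return margin


def predict_proba(model: GBDTModel, X: np.ndarray) -> np.ndarray:
    """Class-1 probability: sigmoid of the accumulated margin."""
    return _sigmoid(predict_margin(model, X))


def log_loss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


# ---------------------------------------------------------------------------
# model selection & evaluation
# ---------------------------------------------------------------------------


def stratified_kfold(y: np.ndarray, k: int, seed: int = 0):
    """Deterministic stratified fold assignment; yields (train_idx, test_idx)."""
    y = np.asarray(y)
    folds = np.zeros(len(y), dtype=np.int64)
    rng = np.random.default_rng(seed)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has fewer members than folds")
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % k
    for f in range(k):
        yield np.flatnonzero(folds != f), np.flatnonzero(folds == f)


def f1_scores(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Per-class F1 and macro average for binary labels."""
    out = {}
    for cls in (0, 1):
        tp = int(np.sum((y_pred == cls) & (y_true == cls)))
        fp = int(np.sum((y_pred == cls) & (y_true != cls)))
        fn = int(np.sum((y_pred != cls) & (y_true == cls)))
        denom = 2 * tp + fp + fn
        out[cls] = 2 * tp / denom if denom else 0.0
    out["macro"] = 0.5 * (out[0] + out[1])
    return out


def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with tie averaging."""
    from scipy.stats import rankdata

    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        return math.nan
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def evaluate_classifier(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict:
    """AUC, accuracy and F1 (overall macro + per class) at the given cut."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(np.int64)
    f1 = f1_scores(y, pred)
    return {
        "auc": auc_rank(y, s),
        "accuracy": float((pred == y).mean()),
        "f1_macro": f1["macro"],
        "f1_class0": f1[0],
        "f1_class1": f1[1],
    }


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict,
    folds: int = 3,
    seed: int = 0,
) -> tuple[TrainConfig, list]:
    """Grid search maximizing mean CV F1-macro over stratified folds.

    ``grid`` maps TrainConfig field names to candidate value lists; ties
    break to the earlier candidate in enumeration order.  Returns the best
    config and the full CV table."""
    if not grid:
        raise ValueError("empty grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(np.int64)
    keys = list(grid)
    table = []
    best = None
    split = list(stratified_kfold(y, folds, seed=seed))
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        cfg = TrainConfig(**{**params, "seed": seed})
        scores = []
        for tr, te in split:
            model = fit_gbdt(X[tr], y[tr], cfg)
            pred = (predict_proba(model, X[te]) >= 0.5).astype(np.int64)
            scores.append(f1_scores(y[te], pred)["macro"])
        mean = float(np.mean(scores))
        table.append({**params, "mean_f1_macro": mean, "fold_scores": scores})
        if best is None or mean > best[0] + 1e-15:
            best = (mean, cfg)
    return best[1], table


def make_pair_labels(
    layer_a: np.ndarray,
    layer_b: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-cell synergy(1)/trade-off(0) labels for an ES pair.

    A cell is labelled synergy when the two layers' deviations from their
    medians share a sign (both above or both below), trade-off when the
    signs oppose.  Cells sitting exactly on either median are dropped.

    Returns (labels, keep_mask_over_input_cells, n_dropped).
    """
    a = np.asarray(layer_a, dtype=float)
    b = np.asarray(layer_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("layer shape mismatch")
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if np.ptp(a[np.isfinite(a)]) == 0 or np.ptp(b[np.isfinite(b)]) == 0:
        raise ValueError("constant layer cannot be labelled")
    da = a - np.nanmedian(a)
    db = b - np.nanmedian(b)
    keep = np.isfinite(da) & np.isfinite(db) & (da != 0) & (db != 0)
    labels = ((da > 0) == (db > 0)).astype(np.int64)
    return labels[keep], keep, int((~keep).sum())
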