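"""From-scratch classifiers: weighted decision tree, multiclass boosting
(SAMME form), bagging, stacking, classical baselines, and grid search.

The boosting loop is the package's centerpiece.  With K classes and
per-row weights W (initialized 1/n and kept normalized):

    Error_i = sum_j W_j 1(C_i(x_j) != y_j) / sum_j W_j
    a_i     = learning_rate * ( ln((1 - Error_i)/Error_i) + ln(K - 1) )
    W_j    <- W_j * exp(a_i * 1(C_i(x_j) != y_j));  W <- W / sum(W)

and prediction is the weighted plurality vote
argmax_k sum_i a_i 1(C_i(x) = k).  The ln(K-1) term keeps a_i positive
exactly while a learner beats random guessing (Error < (K-1)/K); with
K = 2 the coefficient reduces to the classic ln((1-e)/e).  A round with
zero error keeps its learner (with a large capped coefficient) and stops;
a round at or above (K-1)/K discards the learner and stops.

Ties are broken everywhere toward the earliest class in the model's
declared class order (sorted unique labels at fit time); grid-search
ties toward the first combination in declared grid order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .errors import DataError, FitError, ParameterError, SplitError

__all__ = [
    "TreeNode",
    "DecisionTree",
    "fit_tree",
    "BoostModel",
    "boost_fit",
    "boost_predict",
    "BaggingModel",
    "bagging_fit",
    "bagging_predict",
    "StackingModel",
    "stacking_fit",
    "stacking_predict",
    "LogisticRegression",
    "LinearSVM",
    "classical_fits",
    "GridResult",
    "grid_search_cv",
    "stratified_kfold",
]

_ZERO_ERROR_LOGIT = math.log(1e12)  # cap for ln((1-e)/e) when e == 0


# ---------------------------------------------------------------------------
# Weighted CART decision tree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """One node: an internal split or a leaf class distribution."""

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    dist: np.ndarray | None = None  # leaf: probability over model classes

    @property
    def is_leaf(self) -> bool:
        return self.dist is not None


def _gini(wcounts: np.ndarray) -> float:
    tot = wcounts.sum()
    if tot <= 0:
        return 0.0
    p = wcounts / tot
    return float(1.0 - np.sum(p * p))


def _best_split(X, yi, w, n_classes, min_leaf):
    """Scan all features/midpoint thresholds for the minimum weighted Gini."""
    n, d = X.shape
    parent_counts = np.zeros(n_classes)
    np.add.at(parent_counts, yi, w)
    best = (None, None, _gini(parent_counts))
    for j in range(d):
        order = np.argsort(X[:, j], kind="mergesort")
        xs, ys, ws = X[order, j], yi[order], w[order]
        left = np.zeros(n_classes)
        right = parent_counts.copy()
        wl = 0.0
        wr = float(w.sum())
        for i in range(n - 1):
            left[ys[i]] += ws[i]
            right[ys[i]] -= ws[i]
            wl += ws[i]
            wr -= ws[i]
            if xs[i] == xs[i + 1]:
                continue
            if i + 1 < min_leaf or n - i - 1 < min_leaf:
                continue
            score = (wl * _gini(left) + wr * _gini(right)) / (wl + wr)
            if score < best[2] - 1e-12:
                thr = (xs[i] + xs[i + 1]) / 2.0
                # the midpoint of two adjacent floats can round onto the
                # upper value; any threshold in [xs[i], xs[i+1]) splits
                # identically under <=, so fall back to the lower value
                if not xs[i] <= thr < xs[i + 1]:
                    thr = xs[i]
                best = (j, thr, score)
    return best[0], best[1]


def _grow(X, yi, w, n_classes, depth, max_depth, min_leaf):
    counts = np.zeros(n_classes)
    np.add.at(counts, yi, w)
    total = counts.sum()
    dist = counts / total if total > 0 else np.full(n_classes, 1.0 / n_classes)
    if (
        (max_depth is not None and depth >= max_depth)
        or np.count_nonzero(counts) <= 1
        or len(yi) < 2 * min_leaf
    ):
        return TreeNode(dist=dist)
    j, thr = _best_split(X, yi, w, n_classes, min_leaf)
    if j is None:
        return TreeNode(dist=dist)
    mask = X[:, j] <= thr
    if mask.all() or not mask.any():  # degenerate split: refuse to recurse
        return TreeNode(dist=dist)
    left = _grow(X[mask], yi[mask], w[mask], n_classes, depth + 1, max_depth, min_leaf)
    right = _grow(X[~mask], yi[~mask], w[~mask], n_classes, depth + 1, max_depth, min_leaf)
    return TreeNode(feature=j, threshold=thr, left=left, right=right)


@dataclass
class DecisionTree:
    """Greedy binary CART with per-row weights (Gini impurity).

    Candidate thresholds are midpoints of sorted unique feature values;
    growth stops at ``max_depth``, ``min_leaf``, or a pure node.
    """

    max_depth: int | None = None
    min_leaf: int = 1
    classes_: np.ndarray | None = None
    root: TreeNode | None = None

    def fit(self, X, y, sample_weight=None) -> "DecisionTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) == 0:
            raise FitError("cannot fit a tree on an empty dataset")
        if not np.all(np.isfinite(X)):
            raise DataError("features must be finite")
        self.classes_ = np.unique(y)
        yi = np.searchsorted(self.classes_, y)
        w = (
            np.full(len(y), 1.0 / len(y))
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float) / np.sum(sample_weight)
        )
        self.root = _grow(X, yi, w, len(self.classes_), 0, self.max_depth, self.min_leaf)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), len(self.classes_)))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.dist
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_tree(X, y, sample_weight=None, max_depth=None, min_leaf: int = 1) -> DecisionTree:
    """Fit a weighted decision tree; see :class:`DecisionTree`."""
    return DecisionTree(max_depth=max_depth, min_leaf=min_leaf).fit(X, y, sample_weight)


# ---------------------------------------------------------------------------
# Boosting (multiclass, SAMME-form coefficients)
# ---------------------------------------------------------------------------


@dataclass
class BoostModel:
    """Ordered weak learners with vote coefficients."""

    learners: list[DecisionTree]
    coefficients: list[float]
    classes: np.ndarray
    learning_rate: float
    M: int
    fallback_class: Any = None  # used only if every learner was discarded
    weight_history: list[np.ndarray] = field(default_factory=list)  # W after each round


def boost_coefficient(error: float, n_classes: int, learning_rate: float = 1.0) -> float:
    """a = lr * (ln((1-e)/e) + ln(K-1)), capped for e == 0."""
    if error <= 0:
        logit = _ZERO_ERROR_LOGIT
    else:
        logit = math.log((1.0 - error) / error)
    return learning_rate * (logit + math.log(n_classes - 1))


def boost_fit(
    X,
    y,
    M: int = 10,
    learning_rate: float = 1.0,
    max_depth: int | None = 6,
    min_leaf: int = 3,
) -> BoostModel:
    """Fit the boosted ensemble of at most ``M`` weighted trees."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if M < 1:
        raise ParameterError("M must be >= 1")
    classes = np.unique(y)
    K = len(classes)
    if K < 2:
        raise FitError("boosting needs at least 2 classes in y")
    n = len(y)
    W = np.full(n, 1.0 / n)
    learners: list[DecisionTree] = []
    coeffs: list[float] = []
    history: list[np.ndarray] = []
    majority = classes[np.argmax([np.sum(y == c) for c in classes])]
    for _ in range(M):
        tree = fit_tree(X, y, sample_weight=W, max_depth=max_depth, min_leaf=min_leaf)
        miss = tree.predict(X) != y
        error = float(np.sum(W * miss) / np.sum(W))
        if error >= (K - 1) / K:
            break  # worse than chance: discard this learner and stop
        a = boost_coefficient(error, K, learning_rate)
        learners.append(tree)
        coeffs.append(a)
        if error == 0:
            break  # perfect learner: keep it and stop
        W = W * np.exp(a * miss)
        W = W / np.sum(W)
        history.append(W.copy())
    return BoostModel(
        learners=learners,
        coefficients=coeffs,
        classes=classes,
        learning_rate=learning_rate,
        M=M,
        fallback_class=majority,
        weight_history=history,
    )


def boost_predict(model: BoostModel, X) -> np.ndarray:
    """Weighted plurality vote; ties -> earliest class in declared order."""
    X = np.asarray(X, dtype=float)
    if not model.learners:
        return np.full(len(X), model.fallback_class, dtype=model.classes.dtype)
    scores = np.zeros((len(X), len(model.classes)))
    for tree, a in zip(model.learners, model.coefficients):
        pred = tree.predict(X)
        votes = np.searchsorted(model.classes, pred)
        scores[np.arange(len(X)), votes] += a
    return model.classes[np.argmax(scores, axis=1)]  # argmax takes the first max


# ---------------------------------------------------------------------------
# Bagging
# ---------------------------------------------------------------------------


@dataclass
class BaggingModel:
    learners: list[DecisionTree]
    classes: np.ndarray


def bagging_fit(
    X,
    y,
    n_estimators: int = 10,
    max_samples: int | None = None,
    max_depth: int | None = None,
    min_leaf: int = 1,
    seed: int = 0,
) -> BaggingModel:
    """Bootstrap-resampled trees; ``max_samples`` rows drawn with replacement."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if max_samples is None:
        max_samples = n
    if max_samples < 1:
        raise ParameterError("max_samples must be >= 1")
    if max_samples > n:
        raise ParameterError(f"max_samples {max_samples} exceeds n rows {n}")
    rng = np.random.default_rng(seed)
    learners = []
    for _ in range(n_estimators):
        idx = rng.integers(0, n, size=max_samples)
        while len(np.unique(y[idx])) < 1:  # pragma: no cover - never with max_samples>=1
            idx = rng.integers(0, n, size=max_samples)
        learners.append(fit_tree(X[idx], y[idx], max_depth=max_depth, min_leaf=min_leaf))
    return BaggingModel(learners=learners, classes=np.unique(y))


def bagging_predict(model: BaggingModel, X) -> np.ndarray:
    """Unweighted majority vote; ties -> earliest class."""
    X = np.asarray(X, dtype=float)
    counts = np.zeros((len(X), len(model.classes)))
    for tree in model.learners:
        pred = tree.predict(X)
        # a member tree may not have seen every class
        idx = np.searchsorted(model.classes, pred)
        counts[np.arange(len(X)), idx] += 1
    return model.classes[np.argmax(counts, axis=1)]


# ---------------------------------------------------------------------------
# Classical baselines: logistic regression (IRLS) and linear SVM
# ---------------------------------------------------------------------------


class _Standardizer:
    def fit(self, X):
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.std_[self.std_ == 0] = 1.0
        return self

    def transform(self, X):
        return (X - self.mean_) / self.std_


class LogisticRegression:
    """One-vs-rest logistic regression fit by IRLS with a small L2 ridge."""

    def __init__(self, l2: float = 1e-4, max_iter: int = 50, tol: float = 1e-8):
        self.l2 = l2
        self.max_iter = max_iter
        self.tol = tol

    def _fit_binary(self, X, t):
        n, d = X.shape
        beta = np.zeros(d + 1)
        A = np.hstack([np.ones((n, 1)), X])
        ridge = self.l2 * np.eye(d + 1)
        ridge[0, 0] = 0.0  # do not penalize the intercept
        for _ in range(self.max_iter):
            z = np.clip(A @ beta, -30, 30)
            p = 1.0 / (1.0 + np.exp(-z))
            Wd = np.maximum(p * (1 - p), 1e-10)
            grad = A.T @ (t - p) - self.l2 * np.r_[0.0, beta[1:]]
            H = (A * Wd[:, None]).T @ A + ridge
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.linalg.norm(step) < self.tol:
                break
        return beta

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise DataError("features must be finite")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise DataError("need at least 2 classes")
        self.scaler_ = _Standardizer().fit(X)
        Xs = self.scaler_.transform(X)
        self.coef_ = np.stack([self._fit_binary(Xs, (y == c).astype(float)) for c in self.classes_])
        return self

    def decision_function(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        A = np.hstack([np.ones((len(Xs), 1)), Xs])
        return A @ self.coef_.T

    def predict_proba(self, X):
        # normalized one-vs-rest sigmoids
        z = np.clip(self.decision_function(X), -30, 30)
        p = 1.0 / (1.0 + np.exp(-z))
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    @property
    def intercept_(self):
        return self.coef_[:, 0]


class LinearSVM:
    """One-vs-rest linear SVM by deterministic subgradient descent on the
    L2-regularized hinge loss (seeded epoch shuffling, fixed epochs).

    The bias is folded into the weight vector as a constant feature so
    the whole parameter follows the same regularized update; the
    returned parameters are the average of the second half of the
    iterates, which damps the oscillation inherent to subgradient steps.
    """

    def __init__(self, l2: float = 1e-2, epochs: int = 200, seed: int = 0):
        self.l2 = l2
        self.epochs = epochs
        self.seed = seed

    def _fit_binary(self, X, t, rng):
        n, d = X.shape
        A = np.hstack([X, np.ones((n, 1))])
        w = np.zeros(d + 1)
        w_avg = np.zeros(d + 1)
        n_avg = 0
        total = self.epochs * n
        step_count = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for i in order:
                step_count += 1
                eta = 1.0 / (self.l2 * step_count)
                if t[i] * (A[i] @ w) < 1:
                    w = (1 - eta * self.l2) * w + eta * t[i] * A[i]
                else:
                    w = (1 - eta * self.l2) * w
                if step_count > total // 2:
                    w_avg += w
                    n_avg += 1
        w_avg /= n_avg
        return w_avg[:d], float(w_avg[d])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise DataError("features must be finite")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise DataError("need at least 2 classes")
        self.scaler_ = _Standardizer().fit(X)
        Xs = self.scaler_.transform(X)
        rng = np.random.default_rng(self.seed)
        fits = [self._fit_binary(Xs, np.where(y == c, 1.0, -1.0), rng) for c in self.classes_]
        self.coef_ = np.stack([w for w, _ in fits])
        self.intercept_ = np.array([b for _, b in fits])
        return self

    def decision_function(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return Xs @ self.coef_.T + self.intercept_

    def predict_proba(self, X):
        # softmax over margins: a monotone score-to-probability map for stacking
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def classical_fits(X, y, seed: int = 0) -> dict[str, Any]:
    """Fit the three scenario-2 baselines: tree, logistic regression, SVM."""
    return {
        "decision_tree": fit_tree(X, y),
        "logistic_regression": LogisticRegression().fit(X, y),
        "svm": LinearSVM(seed=seed).fit(X, y),
    }


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------


@dataclass
class StackingModel:
    base_models: list[Any]
    meta: Any
    classes: np.ndarray


def _clone_and_fit(spec: Callable[[], Any], X, y):
    model = spec()
    return model.fit(X, y) if hasattr(model, "fit") else model


def stacking_fit(
    X,
    y,
    base_specs: Sequence[Callable[[], Any]] | None = None,
    folds: int = 5,
    seed: int = 0,
    meta_max_depth: int | None = 6,
    meta_spec: Callable[[], Any] | None = None,
) -> StackingModel:
    """Stacked generalization over class-probability meta-features.

    Each base spec is a zero-argument factory returning an unfit model
    with ``fit``/``predict_proba``.  Out-of-fold class probabilities of
    every base form the meta-feature matrix (width = n_bases x K); the
    meta-learner (a decision tree by default, any factory via
    ``meta_spec``) is fit on it, then bases are refit on all rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if base_specs is None:
        base_specs = [
            lambda: DecisionTree(max_depth=6),
            lambda: LogisticRegression(),
            lambda: LinearSVM(seed=seed),
        ]
    if len(base_specs) < 2:
        raise ParameterError("stacking needs at least 2 base learners")
    classes = np.unique(y)
    K = len(classes)
    meta_X = np.zeros((len(y), len(base_specs) * K))
    for tr, te in stratified_kfold(y, folds, seed):
        for b, spec in enumerate(base_specs):
            model = _clone_and_fit(spec, X[tr], y[tr])
            proba = model.predict_proba(X[te])
            cols = np.searchsorted(classes, model.classes_)
            meta_X[np.ix_(te, b * K + cols)] = proba
    if meta_spec is None:
        meta = fit_tree(meta_X, y, max_depth=meta_max_depth)
    else:
        meta = _clone_and_fit(meta_spec, meta_X, y)
    bases = [_clone_and_fit(spec, X, y) for spec in base_specs]
    return StackingModel(base_models=bases, meta=meta, classes=classes)


def stacking_predict(model: StackingModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    K = len(model.classes)
    meta_X = np.zeros((len(X), len(model.base_models) * K))
    for b, base in enumerate(model.base_models):
        proba = base.predict_proba(X)
        cols = np.searchsorted(model.classes, base.classes_)
        meta_X[:, b * K + cols] = proba
    return model.meta.predict(meta_X)


# ---------------------------------------------------------------------------
# Cross-validation and grid search
# ---------------------------------------------------------------------------


def stratified_kfold(y, folds: int, seed: int):
    """Seeded stratified k-fold index pairs ``(train_idx, test_idx)``."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        idx = rng.permutation(idx)
        assignments[idx] = np.arange(len(idx)) % folds
    out = []
    for f in range(folds):
        te = np.nonzero(assignments == f)[0]
        tr = np.nonzero(assignments != f)[0]
        out.append((tr, te))
    return out


@dataclass
class GridResult:
    """Exhaustive grid evaluation; ``best`` is the argmax of mean CV
    accuracy (ties -> first in declared grid order)."""

    combinations: list[dict]
    mean_accuracy: list[float]
    fold_accuracy: list[list[float]]
    best: dict = field(init=False)
    best_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        i = int(np.argmax(self.mean_accuracy))
        self.best = self.combinations[i]
        self.best_accuracy = self.mean_accuracy[i]


def grid_search_cv(
    X,
    y,
    grid: dict[str, Sequence],
    fit_fn: Callable[..., Any] = boost_fit,
    predict_fn: Callable[[Any, np.ndarray], np.ndarray] = boost_predict,
    folds: int = 5,
    seed: int = 0,
) -> GridResult:
    """Exhaustive stratified-CV grid search.

    ``grid`` maps parameter names to candidate values; combinations are
    enumerated in declared key order.  A fold whose training part misses
    a class is re-drawn once (new seed); if it still misses one, a
    :class:`SplitError` is raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not grid:
        raise ParameterError("grid must be non-empty")
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    classes = np.unique(y)
    splits = stratified_kfold(y, folds, seed)
    if any(len(np.unique(y[tr])) < len(classes) for tr, _ in splits):
        splits = stratified_kfold(y, folds, seed + 1)
        if any(len(np.unique(y[tr])) < len(classes) for tr, _ in splits):
            raise SplitError("a CV fold is missing a class even after one re-draw")

    keys = list(grid.keys())
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]
    means, per_fold = [], []
    for combo in combos:
        accs = []
        for tr, te in splits:
            model = fit_fn(X[tr], y[tr], **combo)
            accs.append(float(np.mean(predict_fn(model, X[te]) == y[te])))
        per_fold.append(accs)
        means.append(float(np.mean(accs)))
    return GridResult(combinations=combos, mean_accuracy=means, fold_accuracy=per_fold)
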