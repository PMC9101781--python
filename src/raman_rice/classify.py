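"""Discriminant models for the tolerance label: logistic regression and a
Gini/CART random forest, plus the 7:3 evaluation protocol.

The logistic model scores a sample by the linear form
h(w) = w1 x1 + ... + wd xd + b passed through the sigmoid
g(z) = 1 / (1 + e^-z); probabilities at or above the 0.5 threshold map to
class 1.  Fitting maximises the binomial log-likelihood by iteratively
reweighted least squares with a tiny L2 ridge so perfectly separable data
stay finite, after per-feature standardisation on the training statistics.

The forest grows CART trees on bootstrap resamples.  A split of node D on
attribute a is scored by the Gini index
Gini_index(D, a) = sum_v |D^v|/|D| * Gini(D^v) with
Gini(D) = 1 - sum_k p_k^2; the candidate thresholds are the midpoints of
consecutive distinct sorted values and the minimiser wins.  Prediction is a
majority vote over trees, ties resolved toward the lowest class label.
Feature importances accumulate each split's sample-weighted impurity
decrease and are normalised to sum to one across the forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .crests import METADATA_COLUMNS

__all__ = [
    "LinearModel",
    "ForestConfig",
    "DecisionNode",
    "ForestModel",
    "SplitDataset",
    "sigmoid",
    "train_logistic",
    "predict_logistic",
    "gini_impurity",
    "gini_index",
    "best_split",
    "train_cart",
    "predict_tree",
    "train_random_forest",
    "predict_forest",
    "accuracy",
    "train_test_split",
    "stratified_folds",
    "evaluate_grid",
]

_SEED_MOD = 2**31 - 1  # derived seeds stay below 2**31


# ---------------------------------------------------------------------------
# logistic regression


def sigmoid(z):
    """1 / (1 + e^-z), overflow-safe for large |z|."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LinearModel:
    """Standardised-input logistic discriminant."""

    weights: np.ndarray
    bias: float
    threshold: float = 0.5
    center: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale: np.ndarray = field(default_factory=lambda: np.ones(0))
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")


def train_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 500,
    threshold: float = 0.5,
) -> LinearModel:
    """Fit by IRLS (Newton steps on the penalised log-likelihood).

    Features are standardised with training means/standard deviations
    (constant columns get unit scale); the ridge ``l2`` acts on the weights
    only, keeping coefficients finite under perfect separation.  Iteration
    stops at gradient norm ``tol`` or ``max_iter`` steps.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("need two classes to fit a discriminant")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    n, d = Z.shape
    beta = np.zeros(d + 1)  # [bias, weights]
    A = np.hstack([np.ones((n, 1)), Z])
    penalty = np.full(d + 1, l2)
    penalty[0] = 0.0  # bias unpenalised
    converged = False
    for _ in range(max_iter):
        p = sigmoid(A @ beta)
        grad = A.T @ (y - p) - penalty * beta
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-10, None)
        H = (A * w[:, None]).T @ A + np.diag(penalty + 1e-12)
        beta = beta + np.linalg.solve(H, grad)
    return LinearModel(
        weights=beta[1:],
        bias=float(beta[0]),
        threshold=threshold,
        center=center,
        scale=scale,
        converged=converged,
    )


def predict_logistic(model: LinearModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (probability, label); label 1 iff probability >= threshold."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weights.size:
        raise ValueError(
            f"expected {model.weights.size} features, got {X.shape[1]}"
        )
    Z = (X - model.center) / model.scale
    prob = sigmoid(Z @ model.weights + model.bias)
    prob = np.atleast_1d(prob)
    labels = (prob >= model.threshold).astype(int)
    return prob, labels


# ---------------------------------------------------------------------------
# CART / random forest


def gini_impurity(labels: np.ndarray) -> float:
    """1 - sum_k p_k^2 over the class proportions; 0 iff the node is pure."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot measure impurity of an empty node")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - np.sum(p**2))


def gini_index(
    values: np.ndarray, labels: np.ndarray, split_threshold: float
) -> float:
    """Size-weighted child impurity of the binary split value <= threshold."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask = values <= split_threshold
    n_left = int(mask.sum())
    if n_left == 0 or n_left == labels.size:
        raise ValueError("split must produce two nonempty parts")
    frac = n_left / labels.size
    return frac * gini_impurity(labels[mask]) + (1 - frac) * gini_impurity(labels[~mask])


@dataclass
class DecisionNode:
    """A CART node: either an internal (feature, threshold) split or a leaf."""

    impurity: float
    n_samples: int
    leaf_class: int | None = None
    feature: int | None = None
    threshold: float | None = None
    left: "DecisionNode | None" = None
    right: "DecisionNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_class is not None


def _majority(y: np.ndarray) -> int:
    classes, counts = np.unique(y, return_counts=True)
    return int(classes[np.argmax(counts)])  # argmax tie -> first = lowest label


def best_split(
    X: np.ndarray, y01: np.ndarray, features: Sequence[int]
) -> tuple[int, float, float] | None:
    """Exhaustive Gini-index minimisation over midpoint thresholds.

    ``y01`` must be 0/1 encoded.  Returns (feature, threshold, weighted child
    impurity) or None when no feature admits a two-sided split.  Ties are
    broken toward the lower feature index, then the lower threshold, making
    the search deterministic.
    """
    n = y01.size
    best: tuple[float, int, float] | None = None
    for f in features:
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y01[order]
        boundaries = np.nonzero(xs[:-1] < xs[1:])[0]  # split after position i
        if boundaries.size == 0:
            continue
        cum_pos = np.cumsum(ys)
        n_left = boundaries + 1
        pos_left = cum_pos[boundaries]
        n_right = n - n_left
        pos_right = cum_pos[-1] - pos_left
        p1l = pos_left / n_left
        p1r = pos_right / n_right
        gini_l = 1.0 - p1l**2 - (1.0 - p1l) ** 2
        gini_r = 1.0 - p1r**2 - (1.0 - p1r) ** 2
        weighted = (n_left * gini_l + n_right * gini_r) / n
        k = int(np.argmin(weighted))
        score = float(weighted[k])
        thr = float(0.5 * (xs[boundaries[k]] + xs[boundaries[k] + 1]))
        cand = (score, f, thr)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    score, f, thr = best
    return f, thr, score


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 100
    max_depth: int | None = None
    min_samples_split: int = 2
    max_features: int | str = "sqrt"  # 'sqrt' -> ceil(sqrt(d)), 'all', or an int
    bootstrap: bool = True
    seed: int = 0

    def with_seed(self, seed: int) -> "ForestConfig":
        return replace(self, seed=seed % _SEED_MOD)

    def n_features_per_split(self, d: int) -> int:
        if self.max_features == "sqrt":
            return int(np.ceil(np.sqrt(d)))
        if self.max_features == "all":
            return d
        return min(int(self.max_features), d)


def train_cart(
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int | None = None,
    min_samples_split: int = 2,
    max_features: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DecisionNode, np.ndarray]:
    """Grow one CART tree; returns (root, unnormalised impurity decreases).

    At each node the split minimising the Gini index over all midpoint
    candidates wins (a random ``max_features``-subset of attributes is
    considered when given); growth stops on purity, ``max_depth``,
    ``min_samples_split`` or an unsplittable node, which becomes a
    majority-class leaf (ties toward the lowest label).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.size or y.size == 0:
        raise ValueError("X must be 2-D with one row per label and nonempty")
    classes = np.unique(y)
    if classes.size > 2:
        raise ValueError("CART here scores binary labels only")
    y01 = (y == classes.max()).astype(np.int64)
    # y01 only drives split scoring; leaves use the original labels
    d = X.shape[1]
    n_total = y.size
    importances = np.zeros(d)

    def grow(idx: np.ndarray, depth: int) -> DecisionNode:
        sub_y = y[idx]
        impurity = gini_impurity(sub_y)
        node = DecisionNode(impurity=impurity, n_samples=idx.size)
        if (
            impurity == 0.0
            or idx.size < min_samples_split
            or (max_depth is not None and depth >= max_depth)
        ):
            node.leaf_class = _majority(sub_y)
            return node
        if max_features is not None and max_features < d:
            feats = np.sort(rng.choice(d, size=max_features, replace=False))
        else:
            feats = np.arange(d)
        found = best_split(X[idx], y01[idx], feats)
        if found is None:
            node.leaf_class = _majority(sub_y)
            return node
        f, thr, child_impurity = found
        node.feature = f
        node.threshold = thr
        importances[f] += idx.size / n_total * (impurity - child_impurity)
        mask = X[idx, f] <= thr
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    if max_features is not None and max_features < d and rng is None:
        raise ValueError("feature subsampling requires an rng")
    root = grow(np.arange(n_total), 0)
    return root, importances


def predict_tree(root: DecisionNode, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(X.shape[0], dtype=np.int64)
    for i, row in enumerate(X):
        node = root
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        out[i] = node.leaf_class
    return out


@dataclass
class ForestModel:
    trees: list[DecisionNode]
    config: ForestConfig
    n_features: int
    importances: np.ndarray  # normalised to sum to 1 (or all zero)
    oob_accuracy: float | None = None


def train_random_forest(
    X: np.ndarray, y: np.ndarray, config: ForestConfig | None = None
) -> ForestModel:
    """Bagged CART trees with per-split feature subsampling.

    Each tree sees a bootstrap resample of the training rows (same size) and
    considers ceil(sqrt(d)) features per split by default.  Importances are
    the impurity decreases summed over all trees and normalised to 1.
    """
    config = config or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.size or y.size == 0:
        raise ValueError("X must be 2-D with one row per label and nonempty")
    rng = np.random.default_rng(config.seed)
    n, d = X.shape
    k = config.n_features_per_split(d)
    trees: list[DecisionNode] = []
    importances = np.zeros(d)
    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n) if config.bootstrap else np.arange(n)
        root, imp = train_cart(
            X[idx],
            y[idx],
            max_depth=config.max_depth,
            min_samples_split=config.min_samples_split,
            max_features=k if k < d else None,
            rng=rng,
        )
        trees.append(root)
        importances += imp
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return ForestModel(trees=trees, config=config, n_features=d, importances=importances)


def predict_forest(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over trees; vote ties go to the lowest class label."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    votes = np.stack([predict_tree(t, X) for t in model.trees])
    out = np.empty(X.shape[0], dtype=np.int64)
    for i in range(X.shape[0]):
        classes, counts = np.unique(votes[:, i], return_counts=True)
        out[i] = classes[np.argmax(counts)]
    return out


# ---------------------------------------------------------------------------
# evaluation protocol


def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Percent correct, rounded to two decimals (42/47 -> 89.36)."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.size == 0 or predicted.shape != true.shape:
        raise ValueError("label vectors must be nonempty and of equal length")
    return round(100.0 * float(np.mean(predicted == true)), 2)


@dataclass(frozen=True)
class SplitDataset:
    train_index: np.ndarray
    test_index: np.ndarray
    train_fraction: float
    seed: int


def train_test_split(
    table: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify_column: str = "variety_label",
) -> SplitDataset:
    """Stratified random split with an exact global train count.

    The train size is floor(train_fraction * N) globally (156 samples ->
    109 train / 47 test); per-stratum counts are allocated by largest
    remainder so the totals come out exact, and membership is deterministic
    in the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = table[stratify_column].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every stratum needs at least 2 rows")
    n = y.size
    n_train = int(np.floor(train_fraction * n))
    quotas = train_fraction * counts
    base = np.floor(quotas).astype(int)
    base = np.minimum(base, counts - 1)  # keep >= 1 test row per stratum
    remainder = quotas - base
    short = int(n_train - base.sum())
    order = np.argsort(-remainder, kind="stable")  # largest remainder first
    alloc = base.copy()
    pos = 0
    while short > 0:
        cls = order[pos % classes.size]
        if alloc[cls] < counts[cls] - 1:  # keep >= 1 test row per stratum
            alloc[cls] += 1
            short -= 1
        pos += 1
        if pos > 10 * classes.size and short > 0:
            raise ValueError("cannot honour train_fraction with >=1 test row per stratum")
    rng = np.random.default_rng(seed % _SEED_MOD)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls, take in zip(classes, alloc):
        rows = np.nonzero(y == cls)[0]
        perm = rng.permutation(rows)
        train_idx.append(np.sort(perm[:take]))
        test_idx.append(np.sort(perm[take:]))
    return SplitDataset(
        train_index=np.concatenate(train_idx),
        test_index=np.concatenate(test_idx),
        train_fraction=train_fraction,
        seed=seed,
    )


def stratified_folds(
    y: np.ndarray, n_folds: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified K-fold partition as (train, test) index pairs."""
    y = np.asarray(y)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed % _SEED_MOD)
    fold_of = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        rows = rng.permutation(np.nonzero(y == cls)[0])
        fold_of[rows] = np.arange(rows.size) % n_folds
    folds = []
    for f in range(n_folds):
        test = np.nonzero(fold_of == f)[0]
        train = np.nonzero(fold_of != f)[0]
        folds.append((train, test))
    return folds


def evaluate_grid(
    table: pd.DataFrame,
    selectors: dict,
    split: SplitDataset,
    forest: ForestConfig | None = None,
    fit_selector_on_all: bool = False,
) -> pd.DataFrame:
    """The selector x model accuracy grid.

    ``selectors`` maps a method name to a callable ``table -> SelectionResult``.
    Each selector is fitted on the training rows only (leakage-free; set
    ``fit_selector_on_all`` to reproduce whole-table selection), then both
    models are trained on the selected training columns and scored on the
    held-out rows.  The extra column reports the forest's accuracy advantage
    over the logistic model per selector.
    """
    forest = forest or ForestConfig()
    y = table["variety_label"].to_numpy()
    train, test = split.train_index, split.test_index
    rows = []
    n = len(table)
    for name, selector in selectors.items():
        fit_table = table if fit_selector_on_all else table.iloc[train].reset_index(drop=True)
        result = selector(fit_table)
        cols = list(result.selected_columns)
        if not cols:
            rows.append(
                {
                    "Feature Selection": name,
                    "Matrix Dimension": f"{n} x {len(METADATA_COLUMNS)}",
                    "LRM": np.nan,
                    "RFM": np.nan,
                    "Accuracy Improvement": np.nan,
                }
            )
            continue
        X = table[cols].to_numpy(dtype=float)
        lrm = train_logistic(X[train], y[train])
        _, lrm_pred = predict_logistic(lrm, X[test])
        lrm_acc = accuracy(lrm_pred, y[test])
        rfm = train_random_forest(X[train], y[train], forest)
        rfm_acc = accuracy(predict_forest(rfm, X[test]), y[test])
        rows.append(
            {
                "Feature Selection": name,
                "Matrix Dimension": f"{n} x {len(cols) + len(METADATA_COLUMNS)}",
                "LRM": lrm_acc,
                "RFM": rfm_acc,
                "Accuracy Improvement": round(rfm_acc - lrm_acc, 2),
            }
        )
    return pd.DataFrame(rows)
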