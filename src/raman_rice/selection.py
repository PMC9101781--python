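"""Feature-dimensionality reduction for the crest descriptor table.

Three strategies reduce the 28 descriptor columns:

* **SKB** (select K best) scores every column by the mutual information
  between its discretised values and the binary tolerance label,
  I(X;Y) = sum_x sum_y p(x,y) log2[ p(x,y) / (p(x) p(y)) ],
  estimated by the plug-in rule over equal-frequency bins, and keeps the top
  K columns.
* **RFE** (recursive feature elimination) starts from all columns and
  repeatedly drops the one with the lowest random-forest importance,
  recording the stratified cross-validated accuracy of every intermediate
  subset; the subset with the best accuracy wins (ties go to the smaller
  subset).
* **SFM** (select from model) fits the forest once and keeps columns whose
  importance reaches a threshold, by default the mean importance.

Each result reports which of the seven reference crests remain covered and
the selection rates (percent of columns kept, percent of crests covered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crests import DESCRIPTOR_CODES, feature_columns
from .classify import ForestConfig, stratified_folds, train_random_forest, predict_forest

__all__ = [
    "MutualInformationEstimate",
    "SelectionResult",
    "mutual_information",
    "select_k_best",
    "rfe_select",
    "sfm_select",
    "selection_rate",
    "initial_select",
    "selection_table",
]


@dataclass(frozen=True)
class MutualInformationEstimate:
    """Plug-in mutual information (bits) with its empirical tables."""

    value: float
    joint: np.ndarray  # p(x, y), rows = feature bins, cols = label values
    marginal_x: np.ndarray
    marginal_y: np.ndarray


@dataclass(frozen=True)
class SelectionResult:
    method: str  # "Initial" | "SKB" | "RFE" | "SFM"
    selected_columns: tuple[str, ...]
    n_selected: int
    n_total: int
    crest_coverage: Mapping[str, bool]  # crest key ("480") -> any descriptor kept
    crest_select_rate: float  # percent
    feature_select_rate: float  # percent
    scores: Mapping[str, float] = field(default_factory=dict)


def selection_rate(n_selected: int, n_total: int) -> float:
    """100 * n_selected / n_total, rounded to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_selected <= n_total:
        raise ValueError("n_selected must lie in [0, n_total]")
    return round(100.0 * n_selected / n_total, 2)


def _crest_key(column: str) -> str:
    return column.rsplit("_", 1)[0]


def _make_result(
    method: str,
    all_columns: Sequence[str],
    selected: Sequence[str],
    scores: Mapping[str, float],
) -> SelectionResult:
    crests = sorted({_crest_key(c) for c in all_columns}, key=float)
    selected_crests = {_crest_key(c) for c in selected}
    coverage = {k: k in selected_crests for k in crests}
    # keep canonical table order
    ordered = tuple(c for c in all_columns if c in set(selected))
    return SelectionResult(
        method=method,
        selected_columns=ordered,
        n_selected=len(ordered),
        n_total=len(all_columns),
        crest_coverage=coverage,
        crest_select_rate=selection_rate(sum(coverage.values()), len(crests)),
        feature_select_rate=selection_rate(len(ordered), len(all_columns)),
        scores=dict(scores),
    )


def mutual_information(
    feature: np.ndarray, labels: np.ndarray, n_bins: int = 8
) -> MutualInformationEstimate:
    """Mutual information between a continuous feature and discrete labels.

    The feature is discretised into at most ``n_bins`` equal-frequency bins;
    a feature with at most ``n_bins`` distinct values is binned by value
    (duplicate or boundary quantile edges are dropped, never splitting equal
    values across bins).  The labels are used as-is.  The estimate is the
    plug-in double sum over the empirical joint distribution, in bits, with
    the convention 0*log(0) = 0.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    classes, y_idx = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        warnings.warn("labels are constant; mutual information is 0", stacklevel=2)
    uniq = np.unique(feature)
    if uniq.size <= n_bins:
        x_idx = np.searchsorted(uniq, feature)
    else:
        edges = np.unique(np.quantile(feature, np.linspace(0, 1, n_bins + 1)[1:-1]))
        edges = edges[(edges > uniq[0]) & (edges < uniq[-1])]  # strictly interior
        x_idx = np.searchsorted(edges, feature, side="right")
    n_x = int(x_idx.max()) + 1
    joint = np.zeros((n_x, classes.size))
    np.add.at(joint, (x_idx, y_idx), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0  # 0*log(0) := 0
    terms = joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])
    value = float(max(terms.sum(), 0.0))
    return MutualInformationEstimate(value=value, joint=joint, marginal_x=px, marginal_y=py)


def initial_select(table: pd.DataFrame) -> SelectionResult:
    """Identity passthrough: all descriptor columns kept (the 'Initial' row)."""
    cols = feature_columns(table)
    return _make_result("Initial", cols, cols, {})


def select_k_best(table: pd.DataFrame, k: int = 10, n_bins: int = 8) -> SelectionResult:
    """Keep the k columns most informative about the tolerance label.

    Score ties are broken by lexicographic column name so the selection is
    reproducible.
    """
    cols = feature_columns(table)
    if not 1 <= k <= len(cols):
        raise ValueError(f"k must lie in [1, {len(cols)}]")
    y = table["variety_label"].to_numpy()
    scores = {c: mutual_information(table[c].to_numpy(), y, n_bins).value for c in cols}
    ranked = sorted(cols, key=lambda c: (-scores[c], c))
    return _make_result("SKB", cols, ranked[:k], scores)


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, config: ForestConfig, cv_folds: int, seed: int
) -> float:
    folds = stratified_folds(y, cv_folds, seed)
    correct = 0
    for f, (train_idx, test_idx) in enumerate(folds):
        model = train_random_forest(
            X[train_idx], y[train_idx], config.with_seed(seed * 1009 + f)
        )
        pred = predict_forest(model, X[test_idx])
        correct += int((pred == y[test_idx]).sum())
    return correct / y.size


def rfe_select(
    table: pd.DataFrame,
    forest: ForestConfig | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Recursive elimination driven by forest importances.

    One column (the lowest-importance one; importance ties broken by
    dropping the lexicographically first) is removed per iteration until the
    subset is empty, and every intermediate subset's stratified CV accuracy
    is recorded; the most accurate subset is returned, preferring the
    smaller one on ties.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    forest = forest or ForestConfig()
    cols = feature_columns(table)
    y = table["variety_label"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes for RFE")
    current = list(cols)
    best_subset: list[str] = list(cols)
    best_acc = -1.0
    cv_scores: dict[str, float] = {}
    step = 0
    while current:
        X = table[current].to_numpy(dtype=float)
        acc = _cv_accuracy(X, y, forest, cv_folds, seed * 2003 + step)
        cv_scores[str(len(current))] = acc
        if acc >= best_acc:  # >= prefers the later, smaller subset on ties
            best_acc = acc
            best_subset = list(current)
        if len(current) == 1:
            break
        model = train_random_forest(X, y, forest.with_seed(seed * 4001 + step))
        importances = model.importances
        order = sorted(range(len(current)), key=lambda i: (importances[i], current[i]))
        current.pop(order[0])
        step += 1
    return _make_result("RFE", cols, best_subset, {str(k): v for k, v in cv_scores.items()})


def sfm_select(
    table: pd.DataFrame,
    forest: ForestConfig | None = None,
    threshold: float | str = "mean",
    seed: int = 0,
) -> SelectionResult:
    """Keep columns whose forest importance reaches the threshold.

    ``threshold='mean'`` (the default convention) uses the mean importance;
    a float is used verbatim.
    """
    forest = forest or ForestConfig()
    cols = feature_columns(table)
    y = table["variety_label"].to_numpy()
    X = table[cols].to_numpy(dtype=float)
    model = train_random_forest(X, y, forest.with_seed(seed))
    importances = model.importances
    if not np.any(importances > 0):
        warnings.warn("all importances are zero; SFM selects nothing", stacklevel=2)
        return _make_result("SFM", cols, [], dict(zip(cols, importances)))
    cut = float(np.mean(importances)) if threshold == "mean" else float(threshold)
    selected = [c for c, imp in zip(cols, importances) if imp >= cut]
    return _make_result("SFM", cols, selected, dict(zip(cols, importances)))


def selection_table(results: Sequence[SelectionResult]) -> pd.DataFrame:
    """Crest-by-method matrix of kept descriptor codes, plus a totals row.

    Rows are the reference shifts; each cell lists the kept descriptor codes
    for that crest joined by a backslash (e.g. ``p\\wh\\pd``).
    """
    if not results:
        raise ValueError("need at least one selection result")
    crests = sorted(results[0].crest_coverage, key=float)
    data: dict[str, list[str]] = {"Raman Shift/cm-1": list(crests)}
    for res in results:
        cells = []
        for crest in crests:
            codes = [
                code
                for code in DESCRIPTOR_CODES
                if f"{crest}_{code}" in res.selected_columns
            ]
            cells.append("\\".join(codes))
        data[res.method] = cells
    out = pd.DataFrame(data)
    totals = {"Raman Shift/cm-1": "Total"}
    for res in results:
        totals[res.method] = str(res.n_selected)
    return pd.concat([out, pd.DataFrame([totals])], ignore_index=True)
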