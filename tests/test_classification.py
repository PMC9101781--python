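import math

import numpy as np
import pytest

from conftest import make_feature_frame
from raman_rice.classify import (
    DecisionNode,
    ForestConfig,
    ForestModel,
    LinearModel,
    accuracy,
    best_split,
    evaluate_grid,
    gini_impurity,
    gini_index,
    predict_forest,
    predict_logistic,
    predict_tree,
    sigmoid,
    stratified_folds,
    train_cart,
    train_logistic,
    train_random_forest,
    train_test_split,
)
from raman_rice.selection import initial_select, select_k_best


# --- sigmoid / logistic -----------------------------------------------------


def test_sigmoid_closed_forms():
    assert sigmoid(0.0) == 0.5
    assert sigmoid(math.log(3)) == pytest.approx(0.75)
    z = np.linspace(-5, 5, 11)
    np.testing.assert_allclose(sigmoid(-z), 1 - sigmoid(z), atol=1e-12)
    assert sigmoid(1000.0) == pytest.approx(1.0)
    assert sigmoid(-1000.0) == pytest.approx(0.0)


def test_logistic_symmetric_classes_give_zero_bias():
    """An exactly sign-symmetric design (x, y) -> (-x, 1-y) forces b = 0."""
    rng = np.random.default_rng(0)
    v = rng.normal(2.0, 1.5, 200)  # overlapping classes keep weights moderate
    x = np.concatenate([-v, v])
    y = np.repeat([0, 1], 200)
    model = train_logistic(x[:, None], y)
    assert abs(model.bias) < 0.05
    _, pred = predict_logistic(model, x[:, None])
    assert accuracy(pred, y) >= 85.0


def test_logistic_null_labels_give_chance_accuracy():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(400, 3))
    y = rng.integers(0, 2, size=400)
    model = train_logistic(X[:200], y[:200])
    _, pred = predict_logistic(model, X[200:])
    assert 40.0 <= accuracy(pred, y[200:]) <= 60.0


def test_logistic_duplicated_column_keeps_predictions():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(120, 1))
    y = (X[:, 0] + rng.normal(scale=0.5, size=120) > 0).astype(int)
    single = train_logistic(X, y)
    double = train_logistic(np.hstack([X, X]), y)
    p1, l1 = predict_logistic(single, X)
    p2, l2 = predict_logistic(double, np.hstack([X, X]))
    np.testing.assert_allclose(p1, p2, atol=1e-4)
    np.testing.assert_array_equal(l1, l2)


def test_logistic_separable_data_stays_finite():
    X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    y = np.array([0, 0, 1, 1])
    model = train_logistic(X, y)
    assert np.all(np.isfinite(model.weights))


def test_predict_logistic_threshold_convention():
    zero = LinearModel(weights=np.zeros(2), bias=0.0, center=np.zeros(2), scale=np.ones(2))
    prob, labels = predict_logistic(zero, np.ones((3, 2)))
    np.testing.assert_allclose(prob, 0.5)
    assert labels.tolist() == [1, 1, 1]  # probability 0.5 -> class 1 (>= rule)
    almost = LinearModel(weights=np.array([-1.0]), bias=0.0, center=np.zeros(1), scale=np.ones(1))
    _, lab = predict_logistic(almost, np.array([[0.05]]))
    assert lab.tolist() == [0]  # probability just below 0.5
    with pytest.raises(ValueError, match="features"):
        predict_logistic(zero, np.ones((2, 5)))


def test_logistic_agrees_with_sklearn():
    """Same penalised likelihood, independent solver: probabilities match."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(6)
    X = rng.normal(size=(150, 3))
    y = (X @ np.array([1.0, -0.5, 0.2]) + rng.normal(scale=1.0, size=150) > 0).astype(int)
    mine = train_logistic(X, y, l2=1e-4)
    Z = (X - mine.center) / mine.scale
    ref = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000, tol=1e-10).fit(Z, y)
    prob_mine, _ = predict_logistic(mine, X)
    prob_ref = ref.predict_proba(Z)[:, 1]
    np.testing.assert_allclose(prob_mine, prob_ref, atol=1e-3)


# --- Gini / CART ------------------------------------------------------------


def test_gini_impurity_closed_forms():
    assert gini_impurity([1, 1, 1]) == 0.0
    assert gini_impurity([1, 1, 0, 0]) == 0.5
    assert gini_impurity([1, 1, 1, 0]) == pytest.approx(0.375)  # 1 - (9+1)/16
    with pytest.raises(ValueError):
        gini_impurity([])


def test_gini_impurity_range(rng):
    for _ in range(50):
        labels = rng.integers(0, 2, size=rng.integers(1, 30))
        g = gini_impurity(labels)
        assert 0.0 <= g <= 0.5
        assert (g == 0.0) == (np.unique(labels).size == 1)


def test_gini_index_cases():
    values = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([0, 0, 1, 1])
    assert gini_index(values, labels, 2.5) == 0.0  # perfect separation
    mirrored = np.array([0, 1, 0, 1])
    assert gini_index(values, mirrored, 2.5) == pytest.approx(gini_impurity(mirrored))
    # 6-row worked example: left part {0,0,1}, right part {1,1,0}
    v6 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y6 = np.array([0, 0, 1, 1, 1, 0])
    left = gini_impurity([0, 0, 1])
    right = gini_impurity([1, 1, 0])
    assert gini_index(v6, y6, 3.5) == pytest.approx(0.5 * left + 0.5 * right)
    with pytest.raises(ValueError, match="nonempty"):
        gini_index(values, labels, 0.0)


def brute_force_best_split(X, y):
    """Exhaustive search over every (feature, midpoint) candidate."""
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (lo + hi)
            score = gini_index(X[:, f], y, thr)
            cand = (score, f, thr)
            if best is None or cand < best:
                best = cand
    return best


def test_best_split_matches_exhaustive_search(rng):
    """Random 12-row tables, including tied/duplicated values."""
    for _ in range(50):
        X = np.round(rng.normal(size=(12, 3)), 1)  # rounding forces ties
        y = rng.integers(0, 2, size=12)
        if np.unique(y).size < 2:
            continue
        got = best_split(X, y, range(3))
        want = brute_force_best_split(X, y)
        if want is None:
            assert got is None
            continue
        f, thr, score = got
        assert score == pytest.approx(want[0], abs=1e-12)
        # the returned (feature, threshold) achieves the brute-force optimum
        assert gini_index(X[:, f], y, thr) == pytest.approx(want[0], abs=1e-12)


def test_cart_pure_input_is_single_leaf():
    root, importances = train_cart(np.zeros((4, 2)), np.ones(4, dtype=int))
    assert root.is_leaf and root.leaf_class == 1
    assert importances.sum() == 0.0


def test_cart_separable_1d_learns_the_boundary():
    x = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    root, _ = train_cart(x, y)
    assert not root.is_leaf
    assert abs(root.threshold) <= 1.0
    assert root.left.is_leaf and root.right.is_leaf
    assert accuracy(predict_tree(root, x), y) == 100.0


def test_cart_beats_majority_baseline(rng):
    for _ in range(10):
        X = rng.normal(size=(25, 4))
        y = rng.integers(0, 2, size=25)
        root, _ = train_cart(X, y)
        pred = predict_tree(root, X)
        majority = max(np.mean(y == 0), np.mean(y == 1))
        assert np.mean(pred == y) >= majority


# --- forest -----------------------------------------------------------------


def test_single_tree_forest_equals_cart(rng):
    X = rng.normal(size=(40, 5))
    y = (X[:, 0] + 0.3 * rng.normal(size=40) > 0).astype(int)
    forest = train_random_forest(
        X, y, ForestConfig(n_trees=1, bootstrap=False, max_features="all", seed=0)
    )
    root, _ = train_cart(X, y)
    np.testing.assert_array_equal(predict_forest(forest, X), predict_tree(root, X))


def test_forest_importances_normalised(default_table):
    cols = [c for c in default_table.columns if c not in ("sample_name", "variety_label", "sample_number")]
    X = default_table[cols].to_numpy()
    y = default_table["variety_label"].to_numpy()
    model = train_random_forest(X, y, ForestConfig(n_trees=25, seed=5))
    assert model.importances.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(model.importances >= 0)


def test_forest_determinism(rng):
    X = rng.normal(size=(30, 4))
    y = rng.integers(0, 2, size=30)
    cfg = ForestConfig(n_trees=10, seed=77)
    a = train_random_forest(X, y, cfg)
    b = train_random_forest(X, y, cfg)
    np.testing.assert_array_equal(a.importances, b.importances)
    np.testing.assert_array_equal(predict_forest(a, X), predict_forest(b, X))


def test_forest_vote_tie_goes_to_lowest_label():
    leaf0 = DecisionNode(impurity=0.0, n_samples=1, leaf_class=0)
    leaf1 = DecisionNode(impurity=0.0, n_samples=1, leaf_class=1)
    model = ForestModel(
        trees=[leaf0, leaf1], config=ForestConfig(n_trees=2), n_features=1,
        importances=np.zeros(1),
    )
    assert predict_forest(model, np.zeros((1, 1))).tolist() == [0]
    agree = ForestModel(
        trees=[leaf1, leaf1, leaf1], config=ForestConfig(n_trees=3), n_features=1,
        importances=np.zeros(1),
    )
    assert predict_forest(agree, np.zeros((2, 1))).tolist() == [1, 1]


def test_forest_competitive_with_sklearn(rng):
    """An independent forest implementation scores comparably on the same
    train/test split of separable data."""
    from sklearn.ensemble import RandomForestClassifier

    X = rng.normal(size=(160, 6))
    y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(scale=0.4, size=160) > 0).astype(int)
    train, test = np.arange(110), np.arange(110, 160)
    mine = train_random_forest(X[train], y[train], ForestConfig(n_trees=100, seed=0))
    acc_mine = accuracy(predict_forest(mine, X[test]), y[test])
    ref = RandomForestClassifier(n_estimators=100, random_state=0).fit(X[train], y[train])
    acc_ref = accuracy(ref.predict(X[test]), y[test])
    assert abs(acc_mine - acc_ref) <= 10.0
    assert acc_mine >= 75.0


def test_forest_shuffled_labels_scores_near_chance(rng):
    """Label shuffling destroys generalisation: accuracy within 3 binomial SD
    of 50% on a held-out half of n=200."""
    X = rng.normal(size=(200, 6))
    y = rng.integers(0, 2, size=200)
    model = train_random_forest(X[:100], y[:100], ForestConfig(n_trees=40, seed=8))
    acc = accuracy(predict_forest(model, X[100:]), y[100:])
    sd = 100 * math.sqrt(0.25 / 100)
    assert abs(acc - 50.0) <= 3 * sd


# --- accuracy / split / grid ------------------------------------------------


def test_accuracy_values():
    assert accuracy(np.r_[np.ones(42), np.zeros(5)], np.ones(47)) == 89.36
    assert accuracy(np.ones(5), np.ones(5)) == 100.0
    assert accuracy(np.ones(5), np.zeros(5)) == 0.0
    with pytest.raises(ValueError):
        accuracy(np.array([]), np.array([]))


def test_train_test_split_study_design(default_table):
    split = train_test_split(default_table, 0.7, seed=3)
    assert split.train_index.size == 109  # floor(0.7 * 156)
    assert split.test_index.size == 47
    assert set(split.train_index) & set(split.test_index) == set()
    assert len(set(split.train_index) | set(split.test_index)) == 156
    again = train_test_split(default_table, 0.7, seed=3)
    np.testing.assert_array_equal(split.train_index, again.train_index)
    other = train_test_split(default_table, 0.7, seed=4)
    assert not np.array_equal(split.train_index, other.train_index)
    # stratification: both labels in both parts
    y = default_table["variety_label"].to_numpy()
    assert set(y[split.train_index]) == set(y[split.test_index]) == {0, 1}


def test_train_test_split_small_and_invalid():
    frame = make_feature_frame(np.zeros((10, 2)), np.repeat([0, 1], 5), ["480_p", "480_w"])
    split = train_test_split(frame, 0.7, seed=0)
    assert split.train_index.size == 7 and split.test_index.size == 3
    tiny = make_feature_frame(np.zeros((3, 1)), np.array([0, 0, 1]), ["480_p"])
    with pytest.raises(ValueError, match="stratum"):
        train_test_split(tiny, 0.7, seed=0)


def test_stratified_folds_partition(rng):
    y = rng.integers(0, 2, size=37)
    folds = stratified_folds(y, 5, seed=1)
    all_test = np.sort(np.concatenate([t for _, t in folds]))
    np.testing.assert_array_equal(all_test, np.arange(37))
    for train, test in folds:
        assert set(train) & set(test) == set()
        assert set(y[train]) == {0, 1}


def test_evaluate_grid_shape_and_improvement(default_table):
    split = train_test_split(default_table, 0.7, seed=5)
    selectors = {"Initial": initial_select, "SKB": lambda t: select_k_best(t, k=10)}
    grid = evaluate_grid(default_table, selectors, split, forest=ForestConfig(n_trees=25, seed=5))
    assert list(grid["Feature Selection"]) == ["Initial", "SKB"]
    assert grid.shape == (2, 5)
    assert grid.loc[0, "Matrix Dimension"] == "156 x 31"
    assert grid.loc[1, "Matrix Dimension"] == "156 x 13"
    for _, row in grid.iterrows():
        assert row["Accuracy Improvement"] == pytest.approx(row["RFM"] - row["LRM"], abs=0.01)
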