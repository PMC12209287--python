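"""Metric identities, stratified splitting/folding, forest training,
importances, and the Pearson correlation table."""

import numpy as np
import pandas as pd
import pytest

from ordercast import (
    compute_metrics,
    correlation_table,
    feature_importances,
    split_train_test,
    stratified_folds,
    train_forest,
)
from ordercast.exceptions import OrdercastError


def _labels_from_counts(tp, fp, fn, tn):
    truth = [1] * tp + [0] * fp + [1] * fn + [0] * tn
    pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
    return pred, truth


def test_metrics_hand_computed_example():
    cm, m = compute_metrics([1, 1, 1, 0], [1, 1, 0, 0])
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 0, 1)
    assert m.accuracy == pytest.approx(0.75)
    assert m.precision == pytest.approx(2 / 3)
    assert m.recall == pytest.approx(1.0)
    assert m.f1 == pytest.approx(0.8)


def test_metrics_perfect_prediction():
    _, m = compute_metrics([1, 0, 1], [1, 0, 1])
    assert m.accuracy == m.precision == m.recall == m.f1 == 1.0


def test_metrics_near_perfect_small_test_set():
    # one false positive among 53 cases
    pred, truth = _labels_from_counts(tp=14, fp=1, fn=0, tn=38)
    cm, m = compute_metrics(pred, truth)
    assert cm.total == 53
    assert m.accuracy == pytest.approx(0.981, abs=5e-4)
    assert m.precision == pytest.approx(0.933, abs=5e-4)
    assert m.recall == 1.0
    assert m.f1 == pytest.approx(0.966, abs=5e-4)


def test_metrics_zero_denominators_report_zero():
    _, m = compute_metrics([0, 0], [0, 0])
    assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0


def test_metrics_length_mismatch():
    with pytest.raises(OrdercastError):
        compute_metrics([1], [1, 0])


def test_metric_identities_on_random_confusion_matrices():
    """1000 random confusion matrices: all four metrics match direct
    arithmetic to 1e-12 and F1 is the harmonic mean of P and R."""
    rng = np.random.default_rng(1)
    for _ in range(1000):
        tp, fp, fn, tn = rng.integers(0, 40, size=4)
        if tp + fp + fn + tn == 0:
            continue
        pred, truth = _labels_from_counts(tp, fp, fn, tn)
        cm, m = compute_metrics(pred, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        n = tp + fp + fn + tn
        assert abs(m.accuracy - (tp + tn) / n) < 1e-12
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        assert abs(m.precision - prec) < 1e-12
        assert abs(m.recall - rec) < 1e-12
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert abs(m.f1 - f1) < 1e-12


# -- splitting --------------------------------------------------------------

def test_split_stratification_counts():
    labels = np.array([1] * 30 + [0] * 70)
    items = list(range(100))
    train, test, y_tr, y_te = split_train_test(items, labels, 0.30, seed=4)
    assert len(test) == 30 and len(train) == 70
    assert abs(int(y_te.sum()) - 9) <= 1
    assert abs(int((y_te == 0).sum()) - 21) <= 1
    assert sorted(train + test) == items


def test_split_deterministic_and_small_case():
    labels = [0] * 5 + [1] * 5
    items = list(range(10))
    a = split_train_test(items, labels, 0.30, seed=9)
    b = split_train_test(items, labels, 0.30, seed=9)
    assert a[0] == b[0] and a[1] == b[1]
    assert len(a[0]) == 7 and len(a[1]) == 3


def test_split_single_class_errors():
    with pytest.raises(OrdercastError):
        split_train_test(list(range(10)), [1] * 10)


def test_stratified_folds_partition_and_balance():
    labels = np.array([1] * 50 + [0] * 50)
    folds = stratified_folds(labels, n_splits=10, seed=2)
    all_idx = np.concatenate(folds)
    assert sorted(all_idx) == list(range(100))       # exact partition
    for f in folds:
        assert len(f) == 10
        assert labels[f].sum() == 5                  # exact 5/5 per fold
    again = stratified_folds(labels, n_splits=10, seed=2)
    for f1, f2 in zip(folds, again):
        assert np.array_equal(f1, f2)


def test_stratified_folds_small_class_errors():
    with pytest.raises(OrdercastError):
        stratified_folds([1] * 50 + [0] * 5, n_splits=10)


# -- training ---------------------------------------------------------------

def test_forest_deterministic_given_seed():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(80, 4))
    y = (X[:, 0] > 0).astype(int)
    m1 = train_forest(X, y, seed=5, n_trees=20)
    m2 = train_forest(X, y, seed=5, n_trees=20)
    Xnew = rng.normal(size=(30, 4))
    assert np.array_equal(m1.predict_proba(Xnew), m2.predict_proba(Xnew))


def test_forest_fits_separable_data_perfectly():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(-3, 0.3, size=(40, 2)),
                   rng.normal(3, 0.3, size=(40, 2))])
    y = np.array([0] * 40 + [1] * 40)
    m = train_forest(X, y, seed=0, n_trees=25)
    assert (m.predict(X) == y).all()


def test_forest_degenerate_labels_error():
    with pytest.raises(OrdercastError):
        train_forest(np.zeros((10, 2)), [1] * 10)


def test_balanced_class_weights_equalize_total_weight():
    """With 90/10 imbalance, 'balanced' weighting gives each class the
    same total sample weight."""
    from sklearn.utils.class_weight import compute_class_weight
    y = np.array([0] * 90 + [1] * 10)
    w = compute_class_weight("balanced", classes=np.array([0, 1]), y=y)
    assert 90 * w[0] == pytest.approx(10 * w[1])
    m = train_forest(np.arange(100, dtype=float).reshape(-1, 1), y, seed=0,
                     n_trees=10)
    assert m.class_weight == "balanced"


def test_single_tree_reproduces_hand_traced_stump():
    """On 4 one-dimensional points, the best Gini split (found by brute
    enumeration of thresholds) is the one the forest tree uses."""
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 1, 1])

    def gini(groups):
        total = sum(len(g) for g in groups)
        score = 0.0
        for g in groups:
            if not len(g):
                continue
            p = np.mean(g)
            score += (len(g) / total) * (1 - p ** 2 - (1 - p) ** 2)
        return score

    cuts = [(X[i, 0] + X[i + 1, 0]) / 2 for i in range(3)]
    best = min(cuts, key=lambda c: gini([y[X[:, 0] <= c], y[X[:, 0] > c]]))
    assert best == 1.5
    m = train_forest(X, y, seed=3, n_trees=1)
    tree = m.estimators_[0].tree_
    assert tree.threshold[0] == pytest.approx(1.5)
    assert (m.predict(X) == y).all()


# -- importances and correlations -------------------------------------------

def test_importances_sum_to_one_and_sorted():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(100, 3))
    y = (X[:, 1] > 0).astype(int)
    m = train_forest(X, y, seed=1, n_trees=30)
    imp = feature_importances(m, ["a", "b", "c"])
    assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(v >= 0 for v in imp.values())
    assert list(imp.values()) == sorted(imp.values(), reverse=True)
    assert next(iter(imp)) == "b"        # only informative feature first


def test_constant_feature_has_zero_importance():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(100, 3))
    X[:, 2] = 7.0
    y = (X[:, 0] > 0).astype(int)
    m = train_forest(X, y, seed=1, n_trees=30)
    imp = feature_importances(m, ["a", "b", "const"])
    assert imp["const"] == 0.0


def test_importances_require_trained_model():
    from sklearn.ensemble import RandomForestClassifier
    with pytest.raises(OrdercastError):
        feature_importances(RandomForestClassifier(), ["a"])


def test_correlation_table_identities():
    rng = np.random.default_rng(4)
    x = rng.normal(size=200)
    df = pd.DataFrame({"expanded_score": x, "burden_score": -x,
                       "time_requested": rng.normal(size=200),
                       "time_granted": rng.normal(size=200)})
    table = correlation_table(df)
    assert table.loc["expanded_score", "expanded_score"] == pytest.approx(1.0)
    assert table.loc["expanded_score", "burden_score"] == pytest.approx(-1.0)
    assert np.allclose(table.values, table.values.T)


def test_correlation_table_constant_column_undefined():
    df = pd.DataFrame({"expanded_score": [1.0, 1.0, 1.0],
                       "burden_score": [0.1, 0.2, 0.3],
                       "time_requested": [1, 2, 3.0],
                       "time_granted": [1, 2, 2.5]})
    table = correlation_table(df)
    assert np.isnan(table.loc["expanded_score", "burden_score"])


def test_correlation_table_needs_three_cases():
    df = pd.DataFrame({v: [1.0, 2.0] for v in
                       ("expanded_score", "burden_score",
                        "time_requested", "time_granted")})
    with pytest.raises(OrdercastError):
        correlation_table(df)
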