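import json
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from missdriver.mlpipe import (
    FeatureMatrix,
    MedianImputer,
    MinMaxScaler,
    confusion_metrics,
    kfold_cv,
    mean_report,
    metrics,
    minmax_normalize,
    protein_grouped_split,
    select_k_best,
    split_80_20,
    sweep_k,
    train,
)
from missdriver.nn import MLPClassifier, ModelConfig


def make_matrix(x, y, groups=None, onehot=()):
    return FeatureMatrix(
        features=pd.DataFrame(x), labels=np.asarray(y), groups=groups,
        onehot_columns=frozenset(onehot),
    )


def gaussian_blobs(n=200, d=2, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(0.0, 1.0, size=(n, d))
    x[y == 1] += sep
    return x, y


# -------------------------------------------------------------- normalization

def test_minmax_column_closed_form():
    m = make_matrix({"a": [2.0, 4.0, 6.0]}, [0, 1, 1])
    scaled, _ = minmax_normalize(m)
    assert scaled.features["a"].tolist() == [0.0, 0.5, 1.0]


def test_minmax_constant_column_to_zero():
    m = make_matrix({"a": [3.0, 3.0]}, [0, 1])
    scaled, _ = minmax_normalize(m)
    assert scaled.features["a"].tolist() == [0.0, 0.0]


def test_minmax_test_values_clipped_with_warning():
    scaler = MinMaxScaler()
    scaler.fit(pd.DataFrame({"a": [0.0, 10.0]}))
    with pytest.warns(UserWarning, match="clipped"):
        out = scaler.transform(pd.DataFrame({"a": [15.0, -5.0]}))
    assert out["a"].tolist() == [1.0, 0.0]


def test_minmax_onehot_passthrough():
    m = make_matrix(
        {"a": [2.0, 6.0], "ss_H": [0.0, 1.0]}, [0, 1], onehot=("ss_H",)
    )
    scaled, scaler = minmax_normalize(m)
    assert scaled.features["ss_H"].tolist() == [0.0, 1.0]
    assert "ss_H" not in scaler.mins.index


# ---------------------------------------------------------- feature selection

def test_select_k_best_finds_planted_feature():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 200)
    x = {f"noise_{i}": rng.normal(size=200) for i in range(9)}
    x["planted"] = y + rng.normal(0, 0.01, 200)
    df = pd.DataFrame(x)
    assert select_k_best(df, y, k=1) == ["planted"]
    # direct F-statistic oracle confirms the ranking
    from sklearn.feature_selection import f_classif

    scores = f_classif(df.to_numpy(), y)[0]
    assert df.columns[np.argmax(scores)] == "planted"


def test_select_k_all_columns_ordered_by_score():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 100)
    df = pd.DataFrame({"a": rng.normal(size=100), "b": y * 1.0})
    cols = select_k_best(df, y, k=2)
    assert cols[0] == "b" and set(cols) == {"a", "b"}


def test_select_k_duplicate_scores_name_tiebreak():
    y = np.array([0, 1] * 50)
    same = np.arange(100, dtype=float)
    df = pd.DataFrame({"zeta": same, "alpha": same.copy()})
    assert select_k_best(df, y, k=1) == ["alpha"]


def test_select_k_invalid_k():
    df = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.raises(ValueError):
        select_k_best(df, np.array([0, 1]), k=0)


# ---------------------------------------------------------------------- splits

def test_split_80_20_counts_and_determinism():
    labels = np.array([1] * 60 + [0] * 40)
    tr, te = split_80_20(labels, seed=0)
    assert len(tr) == 80 and len(te) == 20
    tr2, te2 = split_80_20(labels, seed=0)
    assert np.array_equal(tr, tr2) and np.array_equal(te, te2)
    # stratification: class proportions preserved within one record
    assert abs(labels[tr].mean() - 0.6) <= 1 / 80


def test_split_80_20_requires_both_classes():
    with pytest.raises(ValueError):
        split_80_20(np.ones(10), seed=0)


def test_protein_grouped_split_no_overlap():
    groups = np.repeat([f"p{i}" for i in range(10)], 10)
    tr, te = protein_grouped_split(groups, seed=0)
    assert set(groups[tr]).isdisjoint(set(groups[te]))
    # 10 equal proteins -> 8/2 protein split
    assert len(set(groups[te])) == 2


def test_protein_grouped_split_two_proteins():
    groups = np.array(["a"] * 5 + ["b"] * 5)
    tr, te = protein_grouped_split(groups, seed=1)
    assert {tuple(sorted(set(groups[tr]))), tuple(sorted(set(groups[te])))} == {
        ("a",), ("b",)
    }


def test_protein_grouped_split_single_protein_errors():
    with pytest.raises(ValueError):
        protein_grouped_split(np.array(["a"] * 10), seed=0)


# --------------------------------------------------------------------- metrics

def test_metrics_perfect_and_chance():
    perfect = confusion_metrics(50, 50, 0, 0)
    assert (
        perfect.sensitivity, perfect.specificity, perfect.accuracy,
        perfect.balanced_accuracy, perfect.mcc,
    ) == (1.0, 1.0, 1.0, 1.0, 1.0)
    chance = confusion_metrics(25, 25, 25, 25)
    assert chance.accuracy == 0.5 and chance.mcc == 0.0


def test_metrics_hand_arithmetic_and_sklearn_oracle():
    r = confusion_metrics(tp=90, tn=30, fp=70, fn=10)
    assert r.sensitivity == pytest.approx(0.9)
    assert r.specificity == pytest.approx(0.3)
    assert r.balanced_accuracy == pytest.approx(0.6)
    # MCC = (90*30 - 70*10)/sqrt(160*100*100*40) = 2000/8000
    assert r.mcc == pytest.approx(0.25)
    from sklearn.metrics import matthews_corrcoef

    y = [1] * 100 + [0] * 100
    pred = [1] * 90 + [0] * 10 + [1] * 70 + [0] * 30
    assert r.mcc == pytest.approx(matthews_corrcoef(y, pred))


def test_metrics_zero_denominator_mcc():
    assert confusion_metrics(10, 0, 0, 10).mcc == 0.0


def test_metrics_permutation_invariance():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 50)
    pred = rng.integers(0, 2, 50)
    proba = rng.random(50)
    a = metrics(y, pred, proba)
    perm = rng.permutation(50)
    b = metrics(y[perm], pred[perm], proba[perm])
    assert a.to_dict() == b.to_dict()


def test_metrics_single_class_auc_flagged():
    r = metrics([1, 1, 1], [1, 0, 1], [0.9, 0.2, 0.8])
    assert r.auc_roc is None and r.auc_pr is None


def test_roc_auc_equals_mann_whitney_u():
    rng = np.random.default_rng(3)
    for _ in range(200):
        n = int(rng.integers(2, 13))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        proba = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        pos = proba[y == 1]
        neg = proba[y == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = u / (len(pos) * len(neg))
        got = metrics(y, (proba >= 0.5).astype(int), proba).auc_roc
        assert got == pytest.approx(expected, abs=1e-12)


# -------------------------------------------------------------------- network

def test_train_separable_matches_logistic_oracle():
    x, y = gaussian_blobs(n=200, sep=6.0, seed=4)
    assert LogisticRegression().fit(x, y).score(x, y) >= 0.99  # oracle
    m = make_matrix({"f0": x[:, 0], "f1": x[:, 1]}, y)
    config = ModelConfig(hidden_units=(8,), seed=4, max_epochs=200)
    model = train(m, config)
    _, pred = model.predict(m.features)
    assert (pred == y).mean() >= 0.99


def test_train_zero_epochs_loss_is_initial_bce():
    x, y = gaussian_blobs(n=50, sep=1.0, seed=5)
    config = ModelConfig(hidden_units=(4,), max_epochs=0, l2=0.0, seed=5,
                         val_fraction=0.0)
    net = MLPClassifier(n_features=2, config=config)
    net.fit(x, y)
    proba = net.predict_proba(x)
    bce = -np.mean(y * np.log(proba) + (1 - y) * np.log(1 - proba))
    assert net.loss(x, y) == pytest.approx(bce, rel=1e-9)


def test_train_same_seed_identical_weights():
    x, y = gaussian_blobs(n=80, sep=2.0, seed=6)
    nets = []
    for _ in range(2):
        net = MLPClassifier(2, ModelConfig(hidden_units=(8,), seed=7, max_epochs=20))
        net.fit(x, y)
        nets.append(net)
    for w1, w2 in zip(nets[0].weights, nets[1].weights):
        assert np.array_equal(w1, w2)


def test_train_aborts_on_divergence():
    x, y = gaussian_blobs(n=60, sep=2.0, seed=8)
    config = ModelConfig(hidden_units=(8,), seed=8, max_epochs=5)
    net = MLPClassifier(2, config)
    net.weights[0][:] = 1e200  # force the L2 penalty to overflow
    with pytest.raises(FloatingPointError):
        net.fit(x, y)


def test_predict_threshold_boundary_positive():
    x, y = gaussian_blobs(n=60, sep=6.0, seed=9)
    m = make_matrix({"f0": x[:, 0], "f1": x[:, 1]}, y)
    model = train(m, ModelConfig(hidden_units=(4,), seed=9, max_epochs=30))
    proba, pred = model.predict(m.features)
    assert np.array_equal(pred, (proba >= 0.5).astype(int))


def test_predict_schema_mismatch_names_columns():
    x, y = gaussian_blobs(n=60, sep=6.0, seed=10)
    m = make_matrix({"f0": x[:, 0], "f1": x[:, 1]}, y)
    model = train(m, ModelConfig(hidden_units=(4,), seed=10, max_epochs=5))
    bad = m.features.rename(columns={"f1": "renamed"})
    with pytest.raises(ValueError, match="f1"):
        model.predict(bad)


def test_predict_row_order_invariant():
    x, y = gaussian_blobs(n=60, sep=3.0, seed=11)
    m = make_matrix({"f0": x[:, 0], "f1": x[:, 1]}, y)
    model = train(m, ModelConfig(hidden_units=(4,), seed=11, max_epochs=10))
    proba, _ = model.predict(m.features)
    perm = np.random.default_rng(0).permutation(len(y))
    proba_perm, _ = model.predict(m.features.iloc[perm])
    assert np.allclose(proba[perm], proba_perm)


# ------------------------------------------------------------ cross-validation

def test_kfold_partition_and_balance():
    x, y = gaussian_blobs(n=100, sep=6.0, seed=12)
    m = make_matrix({"f0": x[:, 0], "f1": x[:, 1]}, y)
    config = ModelConfig(hidden_units=(8,), seed=12, max_epochs=60)
    reports, mean, _ = kfold_cv(m, config, k=5, seed=12)
    sizes = [r.tp + r.tn + r.fp + r.fn for r in reports]
    assert sum(sizes) == 100
    assert max(sizes) - min(sizes) <= 1
    # perfectly separable -> every fold classifies perfectly
    assert all(r.accuracy == 1.0 for r in reports)
    assert mean.accuracy == 1.0


def test_kfold_requires_enough_rows():
    m = make_matrix({"a": [1.0, 2.0, 3.0]}, [0, 1, 1])
    with pytest.raises(ValueError):
        kfold_cv(m, k=10)


def test_sweep_k_single_grid_and_noise_growth():
    rng = np.random.default_rng(13)
    y = rng.integers(0, 2, 300)
    df = {"signal_0": y + rng.normal(0, 0.3, 300),
          "signal_1": y + rng.normal(0, 0.3, 300)}
    for i in range(8):
        df[f"noise_{i}"] = rng.normal(size=300)
    m = make_matrix(df, y)
    config = ModelConfig(hidden_units=(8,), seed=13, max_epochs=40, patience=5)
    best, _ = sweep_k(m, [3], config=config, cv=3, seed=13)
    assert best == 3
    best2, scores = sweep_k(m, [2, 6, 10], config=config, cv=3, seed=13)
    assert best2 <= 6  # noise-only additions don't win


def test_median_imputation_train_only():
    imputer = MedianImputer().fit(pd.DataFrame({"a": [1.0, 3.0, np.nan]}))
    out = imputer.transform(pd.DataFrame({"a": [np.nan, 10.0]}))
    assert out["a"].tolist() == [2.0, 10.0]
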