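"""SMOTE, LOSO folds, metrics and the experiment driver."""

import numpy as np
import pandas as pd
import pytest
from oracles import auc_pair_count, kappa_brute
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from neosleep.features.registry import feature_names
from neosleep.modeling import (
    auc_mann_whitney,
    classification_metrics,
    cohen_kappa,
    confusion_matrix,
    gini_importance,
    loso_folds,
    run_task,
    smote_oversample,
    train_classifier,
)


def toy_matrix(rng, n_subjects=4, n_per=30):
    """Tiny feature matrix with a weakly informative single feature block."""
    rows = []
    for s in range(n_subjects):
        for i in range(n_per):
            label = ["AS", "QS", "CTW"][rng.integers(0, 3)]
            base = {"AS": 0.0, "QS": 1.0, "CTW": 2.0}[label]
            row = {c: rng.standard_normal() for c in feature_names()}
            row["motion_mean"] = base + 0.1 * rng.standard_normal()
            row["label"] = label
            row["subject_id"] = f"S{s}"
            row["epoch_index"] = i
            rows.append(row)
    return pd.DataFrame(rows)


class TestLosoFolds:
    def test_one_fold_per_subject_partition(self, rng):
        df = toy_matrix(rng, n_subjects=8)
        folds = loso_folds(df)
        assert len(folds) == 8
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(len(df)))
        for tr, te in folds:
            assert not set(df["subject_id"].iloc[tr]) & set(df["subject_id"].iloc[te])

    def test_single_subject_rejected(self, rng):
        df = toy_matrix(rng, n_subjects=1)
        with pytest.raises(ValueError):
            loso_folds(df)


class TestSmote:
    def test_balances_counts(self, rng):
        X = rng.standard_normal((14, 3))
        y = np.array(["A"] * 10 + ["B"] * 4)
        Xb, yb = smote_oversample(X, y, k=3, seed=0)
        assert (yb == "A").sum() == (yb == "B").sum() == 10

    def test_already_balanced_unchanged(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array(["A"] * 5 + ["B"] * 5)
        Xb, yb = smote_oversample(X, y, seed=0)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_synthetic_points_on_segments(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.array(["A"] * 30 + ["B"] * 10)
        Xb, yb = smote_oversample(X, y, k=5, seed=3)
        originals = X[y == "B"]
        for p in Xb[len(X):]:
            # p = x + u (x' - x) for some pair of class-B originals
            on_segment = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    d = originals[j] - originals[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    u = (p - originals[i]) @ d / denom
                    proj = originals[i] + u * d
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(proj, p, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_singleton_class_duplicates_with_warning(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array(["A"] * 4 + ["B"])
        with pytest.warns(UserWarning, match="single member"):
            Xb, yb = smote_oversample(X, y, seed=0)
        assert (yb == "B").sum() == 4
        assert np.allclose(Xb[yb == "B"], X[-1])

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.array(["A"] * 15 + ["B"] * 5)
        a = smote_oversample(X, y, seed=7)
        b = smote_oversample(X, y, seed=7)
        assert np.array_equal(a[0], b[0])


class TestClassifier:
    def test_separable_data_perfect_train_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.array(["A"] * 20 + ["B"] * 20)
        model = train_classifier(X, y, seed=0)
        assert (model.predict(X) == y).mean() == 1.0

    def test_same_seed_identical_predictions(self, rng):
        X = rng.standard_normal((60, 5))
        y = rng.choice(["A", "B"], 60)
        Xt = rng.standard_normal((20, 5))
        p1 = train_classifier(X, y, seed=3).predict_proba(Xt)
        p2 = train_classifier(X, y, seed=3).predict_proba(Xt)
        assert np.array_equal(p1, p2)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.empty((0, 3)), np.array([]))


class TestGiniImportance:
    def test_label_leak_ranked_first(self, rng):
        n = 200
        y = rng.choice(["A", "B"], n)
        X = rng.standard_normal((n, 5))
        X[:, 2] = (y == "A").astype(float)  # feature 2 equals the label
        model = train_classifier(X, y, seed=0)
        df = gini_importance([model.feature_importances_], [f"f{i}" for i in range(5)])
        assert df.iloc[0]["feature"] == "f2"

    def test_importances_sum_to_one(self, rng):
        X = rng.standard_normal((80, 6))
        y = rng.choice(["A", "B"], 80)
        model = train_classifier(X, y, seed=1)
        assert model.feature_importances_.sum() == pytest.approx(1.0)

    def test_top10_report(self, rng):
        arr = [rng.random(20) for _ in range(3)]
        df = gini_importance(arr, [f"f{i}" for i in range(20)])
        assert len(df.head(10)) == 10


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(np.array([[50, 0], [0, 50]])) == 1.0

    def test_chance_agreement(self):
        assert cohen_kappa(np.array([[25, 25], [25, 25]])) == 0.0

    def test_hand_formula_and_sklearn(self):
        cm = np.array([[40, 10], [20, 30]])
        want = kappa_brute(cm)
        assert cohen_kappa(cm) == pytest.approx(want, abs=1e-12)
        y_true = ["a"] * 50 + ["b"] * 50
        y_pred = ["a"] * 40 + ["b"] * 10 + ["a"] * 20 + ["b"] * 30
        assert cohen_kappa(cm) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12
        )

    def test_degenerate_single_class(self):
        assert cohen_kappa(np.array([[10, 0], [0, 0]])) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((2, 2)))


class TestMetrics:
    def test_perfect_predictions(self):
        cm = np.diag([30, 20, 10])
        m = classification_metrics(cm, ["AS", "QS", "CTW"])
        assert m["accuracy"] == 1.0
        for c in ("AS", "QS", "CTW"):
            assert m[f"sensitivity_{c}"] == m[f"precision_{c}"] == m[f"specificity_{c}"] == 1.0

    def test_all_one_class_predictions_hand_computed(self):
        # everything predicted AS: AS precision = prevalence, QS/CTW undefined
        cm = np.array([[30, 0, 0], [20, 0, 0], [10, 0, 0]])
        m = classification_metrics(cm, ["AS", "QS", "CTW"])
        assert m["sensitivity_AS"] == 1.0
        assert m["precision_AS"] == pytest.approx(0.5)
        assert np.isnan(m["precision_QS"]) and np.isnan(m["precision_CTW"])
        assert m["specificity_AS"] == 0.0

    def test_confusion_matrix_row_sums(self, rng):
        y_true = rng.choice(["AS", "QS", "CTW"], 100)
        y_pred = rng.choice(["AS", "QS", "CTW"], 100)
        cm = confusion_matrix(y_true, y_pred, ["AS", "QS", "CTW"])
        for i, c in enumerate(["AS", "QS", "CTW"]):
            assert cm[i].sum() == (y_true == c).sum()


class TestAuc:
    def test_matches_pair_count_oracle_and_sklearn(self, rng):
        for _ in range(5):
            pos = rng.standard_normal(12)
            neg = rng.standard_normal(20) - 0.5
            got = auc_mann_whitney(pos, neg)
            assert got == pytest.approx(auc_pair_count(pos, neg), abs=1e-12)
            y = np.r_[np.ones(12), np.zeros(20)]
            assert got == pytest.approx(roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)

    def test_ties_handled_as_half(self):
        assert auc_mann_whitney([1.0, 1.0], [1.0, 1.0]) == 0.5

    def test_empty_side_missing(self):
        assert np.isnan(auc_mann_whitney([], [1.0]))


class TestRunTask:
    def test_report_structure_and_ranges(self, rng):
        df = toy_matrix(rng, n_subjects=4, n_per=40)
        rep = run_task(df, "Motion", "3class", seed=0, n_estimators=30)
        assert rep.pooled_cm.sum() == len(df)
        assert len(rep.per_fold_kappa) == 4
        assert -1.0 <= rep.mean_kappa <= 1.0
        assert 0.0 <= rep.pooled_metrics["accuracy"] <= 1.0
        # row sums equal true class counts
        for i, c in enumerate(rep.classes):
            assert rep.pooled_cm[i].sum() == (df["label"] == c).sum()

    def test_binary_task_auc_reported(self, rng):
        df = toy_matrix(rng, n_subjects=3, n_per=40)
        rep = run_task(df, "Motion", "AS_vs_QS", seed=0, n_estimators=30)
        assert 0.0 <= rep.pooled_auc <= 1.0
        assert len(rep.per_fold_auc) == 3

    def test_deterministic_reports(self, rng):
        df = toy_matrix(rng, n_subjects=3, n_per=30)
        a = run_task(df, "Motion", "3class", seed=5, n_estimators=20)
        b = run_task(df, "Motion", "3class", seed=5, n_estimators=20)
        assert a.per_fold_kappa == b.per_fold_kappa
        assert np.array_equal(a.pooled_cm, b.pooled_cm)
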