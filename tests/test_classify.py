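import numpy as np
import pandas as pd
import pytest

from canegait.classify import (
    REPORTED_CONFUSION, ConfusionMatrix, ZScoreScaler, assign_folds,
    build_estimator, default_model_specs, hyperparameter_search,
    metrics_from_confusion, roc_auc, run_classification, train_eval_cv,
    zscore_fit_apply,
)
from canegait.errors import DataError, SingleClassFoldError
from canegait.io import FEATURE_COLUMNS, default_config


def _cluster_table(n_per_class=60, gap_sd=5.0, seed=0):
    """Linearly separable two-cluster synthetic feature table."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, center in (("frail", 0.0), ("robust", gap_sd)):
        X = rng.normal(center, 1.0, size=(n_per_class, len(FEATURE_COLUMNS)))
        for i, x in enumerate(X):
            rows.append({"trial_id": f"{label}{i}", "subject_id": f"{label}{i}",
                         "frail_label": label, **dict(zip(FEATURE_COLUMNS, x))})
    return pd.DataFrame(rows).sample(frac=1, random_state=seed).reset_index(drop=True)


class TestZScore:
    def test_train_equals_apply(self, rng):
        X = rng.normal(3, 2, size=(40, 4))
        Z, mean, sd = zscore_fit_apply(X, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, rtol=1e-12)

    def test_constant_column_warns_and_zeroes(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            Z, _, _ = zscore_fit_apply(X, X)
        np.testing.assert_allclose(Z[:, 0], 0.0)

    def test_sample_sd_convention(self):
        # train {0, 10}: mean 5, sample sd sqrt(50); apply 5 -> 0
        Z, mean, sd = zscore_fit_apply(np.array([[0.0], [10.0]]), np.array([[5.0]]))
        assert Z[0, 0] == pytest.approx(0.0)
        assert sd[0] == pytest.approx(np.sqrt(50.0))


class TestAssignFolds:
    def test_trial_random_131_fold_sizes(self):
        fa = assign_folds(131, n_folds=10, seed=3)
        sizes = sorted(np.bincount(fa.folds, minlength=10))
        assert sizes == [13] * 9 + [14]

    def test_subject_grouped_no_subject_spans_folds(self, cohort):
        fa = assign_folds(cohort["table"], mode="subject-grouped", seed=1)
        table = cohort["table"]
        spans = table.groupby("subject_id").apply(
            lambda g: len(np.unique(fa.folds[g.index])), include_groups=False)
        assert (spans == 1).all()

    def test_same_seed_identical(self, cohort):
        a = assign_folds(cohort["table"], seed=5)
        b = assign_folds(cohort["table"], seed=5)
        assert np.array_equal(a.folds, b.folds)

    def test_too_few_trials_rejected(self):
        with pytest.raises(DataError):
            assign_folds(7, n_folds=10)


class TestConfusionMetrics:
    def test_reported_svm_counts_reproduce_printed_metrics(self):
        """The all-positive SVM matrix gives 71.8% accuracy, 83.6% F1."""
        cm = ConfusionMatrix(**REPORTED_CONFUSION["SVM"], positive_label="robust")
        m = metrics_from_confusion(cm)
        assert round(100 * m["accuracy"], 1) == 71.8
        assert round(100 * m["f1"], 1) == 83.6
        assert m["recall"] == 1.0

    def test_reported_dt_counts_near_printed_f1(self):
        cm = ConfusionMatrix(**REPORTED_CONFUSION["DT"], positive_label="robust")
        m = metrics_from_confusion(cm)
        assert 100 * m["f1"] == pytest.approx(91.8, abs=0.2)

    def test_perfect_matrix(self):
        m = metrics_from_confusion(ConfusionMatrix(10, 0, 0, 10))
        assert m == {"accuracy": 1.0, "precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_undefined_ratios_reported_absent(self):
        m = metrics_from_confusion(ConfusionMatrix(0, 0, 0, 10))
        assert m["precision"] is None and m["recall"] is None and m["f1"] is None
        assert m["accuracy"] == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(DataError):
            metrics_from_confusion(ConfusionMatrix(0, 0, 0, 0))

    def test_f1_invariant_under_precision_recall_swap(self, rng):
        """Transposing fp and fn swaps P and R but leaves F1 unchanged."""
        for _ in range(10):
            tp, fp, fn, tn = rng.integers(1, 50, 4)
            f1 = metrics_from_confusion(ConfusionMatrix(tp, fp, fn, tn))["f1"]
            f1_swapped = metrics_from_confusion(ConfusionMatrix(tp, fn, fp, tn))["f1"]
            assert f1 == pytest.approx(f1_swapped)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], ["frail", "frail", "robust", "robust"])
        assert auc == 1.0

    def test_constant_scores_auc_half(self):
        _, auc = roc_auc([0.5] * 10, ["frail"] * 4 + ["robust"] * 6)
        assert auc == 0.5

    def test_matches_pairwise_enumeration(self, rng):
        """Rank AUC equals the O(n^2) positive-negative pair count."""
        for _ in range(20):
            scores = np.round(rng.normal(size=12), 1)  # ties likely
            labels = np.array(["frail"] * 5 + ["robust"] * 7)
            rng.shuffle(labels)
            if len(set(labels)) < 2:
                continue
            _, auc = roc_auc(scores, labels)
            pos, neg = scores[labels == "frail"], scores[labels == "robust"]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.4, "frail", "robust")
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], ["frail", "frail"])


class TestTrainEvalCv:
    @pytest.mark.parametrize("model", ["DT", "LDA", "KNN", "SVM", "BOOST"])
    def test_separable_clusters_high_accuracy(self, model):
        """Any family reaches >= 95% on 5-sd-gap clusters."""
        table = _cluster_table()
        X = table[list(FEATURE_COLUMNS)].to_numpy(float)
        y = table["frail_label"].to_numpy()
        folds = assign_folds(table, seed=0)
        res = train_eval_cv(X, y, default_model_specs()[model], folds, seed=0)
        assert res.fold_means["accuracy"] >= 0.95

    def test_aggregated_total_equals_n_trials(self):
        table = _cluster_table(n_per_class=30)
        X = table[list(FEATURE_COLUMNS)].to_numpy(float)
        y = table["frail_label"].to_numpy()
        res = train_eval_cv(X, y, default_model_specs()["DT"],
                            assign_folds(table, seed=1), seed=1)
        assert res.aggregated.total == len(table)

    def test_permuted_labels_near_chance_auc(self):
        """Destroying the labels pushes AUC toward 0.5."""
        rng = np.random.default_rng(2)
        aucs = []
        for s in range(10):
            table = _cluster_table(n_per_class=30, seed=s)
            table["frail_label"] = rng.permutation(table["frail_label"].to_numpy())
            X = table[list(FEATURE_COLUMNS)].to_numpy(float)
            y = table["frail_label"].to_numpy()
            res = train_eval_cv(X, y, default_model_specs()["DT"],
                                assign_folds(table, seed=s), seed=s)
            aucs.append(res.fold_means["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_single_class_training_split_rejected(self):
        X = np.zeros((12, 3))
        y = np.array(["frail"] * 6 + ["robust"] * 6)
        folds = assign_folds(12, n_folds=2, seed=0)
        folds.folds = np.array([0] * 6 + [1] * 6)  # fold 0 trains on robust only
        with pytest.raises(SingleClassFoldError):
            train_eval_cv(X, y, default_model_specs()["DT"], folds)

    def test_per_fold_f1_is_harmonic_mean_of_p_and_r(self):
        table = _cluster_table(n_per_class=40, gap_sd=1.0, seed=4)
        X = table[list(FEATURE_COLUMNS)].to_numpy(float)
        y = table["frail_label"].to_numpy()
        res = train_eval_cv(X, y, default_model_specs()["LDA"],
                            assign_folds(table, seed=4), seed=4)
        for _, row in res.per_fold.iterrows():
            if row["precision"] and row["recall"]:
                hm = 2 * row.precision * row.recall / (row.precision + row.recall)
                assert row.f1 == pytest.approx(hm)


class TestHyperparameterSearch:
    def _data(self):
        table = _cluster_table(n_per_class=40, gap_sd=2.0, seed=7)
        X = table[list(FEATURE_COLUMNS)].to_numpy(float)
        y = table["frail_label"].to_numpy()
        return X, y, assign_folds(table, seed=7)

    def test_budget_one_returns_default(self):
        X, y, folds = self._data()
        spec = default_model_specs()["KNN"]
        tuned = hyperparameter_search(spec, X, y, folds, budget=1)
        assert tuned.params == spec.params

    def test_deterministic_under_seed(self):
        X, y, folds = self._data()
        spec = default_model_specs()["SVM"]
        a = hyperparameter_search(spec, X, y, folds, seed=3, budget=8)
        b = hyperparameter_search(spec, X, y, folds, seed=3, budget=8)
        assert a.params == b.params

    def test_tuned_loss_no_worse_than_default(self):
        """The argmin over a superset containing the default can't be worse."""
        X, y, folds = self._data()
        spec = default_model_specs()["KNN"]
        tuned = hyperparameter_search(spec, X, y, folds, seed=1, budget=10)
        loss = lambda s: 1 - train_eval_cv(X, y, s, folds).fold_means["accuracy"]
        assert loss(tuned) <= loss(spec) + 1e-12


class TestRunClassification:
    def test_all_five_models_reported(self, cohort):
        report = run_classification(cohort["table"], default_config(), seed=1)
        assert set(report.results) == {"DT", "LDA", "KNN", "SVM", "BOOST"}
        summary = report.summary_frame()
        assert len(summary) == 5
        assert summary["accuracy_pct"].between(0, 100).all()

    def test_boost_spec_matches_protocol(self):
        spec = default_model_specs()["BOOST"]
        assert spec.params["n_estimators"] == 243
        assert spec.params["learning_rate"] == pytest.approx(0.59256)
        est = build_estimator(spec)
        assert est.max_depth == 1  # logistic-loss boosting of stumps
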