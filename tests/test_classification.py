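import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogniscreen.classification import (
    SVMConfig,
    compare_models,
    compute_metrics,
    cross_validate,
    default_grid,
    fit_svm,
    grid_search,
    roc_auc_ci,
)


class TestSVMConfig:
    def test_paper_style_rbf_config_valid(self):
        cfg = SVMConfig(kernel="rbf", C=1.1, gamma=0.001)
        assert cfg.C == 1.1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SVMConfig(kernel="rbf", C=-1.0)
        with pytest.raises(ValueError):
            SVMConfig(kernel="quadratic")

    def test_default_grid_spans_four_kernels(self):
        kernels = {c.kernel for c in default_grid()}
        assert kernels == {"linear", "rbf", "poly", "sigmoid"}
        # the printed optimum is in the grid
        assert SVMConfig(kernel="rbf", C=1.1, gamma=0.001) in default_grid()


class TestFitSVM:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([-1] * 20 + [1] * 20)
        clf = fit_svm(X, y, SVMConfig(kernel="linear", C=1.0))
        assert (clf.predict(X) == y).all()

    def test_label_flip_flips_decision_sign(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.array([1, -1] * 15)
        s1 = fit_svm(X, y, SVMConfig(kernel="linear", C=1.0)).decision_function(X)
        s2 = fit_svm(X, -y, SVMConfig(kernel="linear", C=1.0)).decision_function(X)
        # agreement is limited by the solver's convergence tolerance
        np.testing.assert_allclose(s1, -s2, atol=5e-3)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single-class"):
            fit_svm(rng.standard_normal((10, 2)), np.ones(10))


class TestMetrics:
    def test_confusion_arithmetic(self):
        m = compute_metrics(tp=43, fn=7, tn=45, fp=5)
        assert m["accuracy"] == pytest.approx(88.0)
        assert m["sensitivity"] == pytest.approx(86.0)
        assert m["specificity"] == pytest.approx(90.0)

    def test_perfect_prediction(self):
        m = compute_metrics(tp=10, fn=0, tn=10, fp=0)
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (100.0, 100.0, 100.0)

    def test_empty_positive_class_flagged(self):
        m = compute_metrics(tp=0, fn=0, tn=10, fp=2)
        assert np.isnan(m["sensitivity"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 1, 0)


class TestROC:
    def test_perfect_ranking_auc_one(self):
        scores = np.array([1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        labels = np.array([1, 1, 1, -1, -1, -1])
        res = roc_auc_ci(scores, labels, n_boot=100, seed=0)
        assert res["auc"] == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.standard_normal(200)
        labels = np.array([1, -1] * 100)
        res = roc_auc_ci(scores, labels, n_boot=100, seed=0)
        assert abs(res["auc"] - 0.5) < 3 * 0.5 / np.sqrt(100)

    def test_auc_equals_mann_whitney_u(self, rng):
        scores = rng.standard_normal(120)
        labels = np.array([1] * 50 + [-1] * 70)
        scores[labels == 1] += 0.8
        res = roc_auc_ci(scores, labels, n_boot=100, seed=0)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == -1]).statistic
        assert res["auc"] == pytest.approx(u / (50 * 70), abs=1e-12)

    def test_auc_invariant_to_monotone_transform(self, rng):
        scores = rng.standard_normal(80)
        labels = np.array([1, -1] * 40)
        a = roc_auc_ci(scores, labels, n_boot=50, seed=0)["auc"]
        b = roc_auc_ci(np.exp(scores), labels, n_boot=50, seed=0)["auc"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_ci_brackets_auc_and_roc_monotone(self, rng):
        scores = rng.standard_normal(100)
        labels = np.array([1, -1] * 50)
        scores[labels == 1] += 1.0
        res = roc_auc_ci(scores, labels, n_boot=500, seed=1)
        assert res["ci_low"] <= res["auc"] <= res["ci_high"]
        assert np.all(np.diff(res["fpr"]) >= 0) and np.all(np.diff(res["tpr"]) >= 0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_ci(np.zeros(5), np.ones(5))


class TestCrossValidate:
    def test_folds_partition_subjects(self, toy_table):
        res = cross_validate(toy_table, SVMConfig(), k=5, seed=0, n_boot=50)
        seen = np.concatenate([a["test_index"] for a in res.artifacts])
        assert sorted(seen) == list(range(len(toy_table)))
        sizes = [len(a["test_index"]) for a in res.artifacts]
        assert all(s == len(toy_table) // 5 for s in sizes)

    def test_informative_table_beats_chance(self, toy_table):
        res = cross_validate(toy_table, SVMConfig(), k=5, seed=0, select_k=10, n_boot=50)
        assert res.summary["accuracy_mean"] > 65.0
        assert res.auc["auc"] > 0.7

    def test_permuted_labels_at_chance(self, toy_table):
        accs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            shuffled = toy_table.labels.copy()
            shuffled[:] = rng.permutation(shuffled.to_numpy())
            from cogniscreen.features_assembly import FeatureTable

            t = FeatureTable(data=toy_table.data, labels=shuffled)
            res = cross_validate(t, SVMConfig(), k=5, seed=seed, n_boot=20)
            accs.append(res.summary["accuracy_mean"])
        se = 100 * 0.5 / np.sqrt(len(toy_table) * len(accs))
        assert abs(np.mean(accs) - 50.0) < 3 * se + 5.0

    def test_too_few_subjects_rejected(self, toy_table):
        from cogniscreen.features_assembly import FeatureTable

        tiny = FeatureTable(data=toy_table.data.iloc[:6], labels=toy_table.labels.iloc[:6])
        with pytest.raises(ValueError):
            cross_validate(tiny, k=5)

    def test_fold_sds_are_over_folds(self, toy_table):
        res = cross_validate(toy_table, SVMConfig(), k=5, seed=0, n_boot=20)
        assert res.summary["accuracy_sd"] == pytest.approx(
            res.fold_metrics["accuracy"].std(ddof=1)
        )


class TestGridSearch:
    def test_single_config_grid_returned(self, toy_table):
        cfg = SVMConfig(kernel="linear", C=0.5)
        best, results = grid_search(toy_table, [cfg], folds=5, seed=0)
        assert best == cfg and len(results) == 1

    def test_tie_break_prefers_smaller_c_then_kernel_order(self, toy_table):
        # strongly separated data: most configs reach the same accuracy
        from cogniscreen.features_assembly import FeatureTable

        data = toy_table.data.copy()
        data.iloc[:, 0] = toy_table.labels * 10.0  # make it trivially separable
        t = FeatureTable(data=data, labels=toy_table.labels)
        grid = [
            SVMConfig(kernel="rbf", C=4.0, gamma=0.1),
            SVMConfig(kernel="linear", C=4.0),
            SVMConfig(kernel="linear", C=0.5),
        ]
        best, results = grid_search(t, grid, folds=5, seed=0)
        top = results["accuracy_mean"].max()
        tied = results[results["accuracy_mean"] == top]
        if len(tied) > 1:
            assert best.C == tied["C"].min()


class TestCompareModels:
    def test_report_has_four_views_per_cohort(self, toy_table):
        rep = compare_models(toy_table, toy_table, seed=0, select_k=None, n_boot=50)
        assert set(rep["views"]) == {"clinical", "ntb_only", "physio_only", "all"}
        for entry in rep["views"].values():
            assert "cv" in entry and "test" in entry
            assert 0.0 <= entry["cv"]["auc"] <= 1.0

    def test_cohort2_perturbation_leaves_fitted_model_identical(self, toy_table):
        from cogniscreen.features_assembly import FeatureTable

        perturbed = FeatureTable(
            data=toy_table.data + 5.0, labels=toy_table.labels
        )
        r1 = compare_models(toy_table, toy_table, seed=0, select_k=5, n_boot=20)
        r2 = compare_models(toy_table, perturbed, seed=0, select_k=5, n_boot=20)
        for view in r1["views"]:
            a1 = r1["views"][view]["_final_artifact"]
            a2 = r2["views"][view]["_final_artifact"]
            np.testing.assert_array_equal(a1["dual_coef"], a2["dual_coef"])
            assert a1["features"] == a2["features"]
            assert a1["norm_mean"] == a2["norm_mean"]
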