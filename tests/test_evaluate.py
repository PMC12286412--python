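"""Evaluation pipeline stages: oracles, guards, determinism."""

import math

import numpy as np
import pytest

from fwf.evaluate import (
    ModelSpec,
    bias_variance_decompose,
    compute_metrics,
    confidence_interval_t,
    cross_validate,
    detect_outliers_robust_pca,
    make_classifier,
    oversample_smote,
    pca_reduce,
    permutation_test,
    pr_baseline,
    temporal_split,
)


class TestRobustPcaOutliers:
    def test_zero_factor_is_identity(self, rng):
        X = rng.normal(size=(50, 4))
        assert detect_outliers_robust_pca(X, 0.0).all()

    def test_removal_count(self, rng):
        X = rng.normal(size=(100, 5))
        mask = detect_outliers_robust_pca(X, 0.2, seed=0)
        assert mask.sum() == 80

    def test_planted_contaminants_removed(self, rng):
        X = rng.normal(size=(100, 6))
        planted = rng.choice(100, size=5, replace=False)
        X[planted] += 10.0  # 10-sigma shift
        mask = detect_outliers_robust_pca(X, 0.05, seed=0)
        assert (~mask[planted]).sum() >= 4

    def test_bad_factor_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_outliers_robust_pca(rng.normal(size=(10, 2)), 1.0)


class TestTemporalSplit:
    def test_counts_and_order(self, rng):
        X = rng.normal(size=(100, 3))
        y = (rng.random(100) < 0.2).astype(int)
        order = np.arange(100)
        (Xtr, ytr), (Xte, yte) = temporal_split((X, y, order))
        assert len(ytr) == 80 and len(yte) == 20
        assert np.array_equal(Xte, X[80:])

    def test_unordered_rows_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.zeros(10, dtype=int)
        order = np.array([0, 2, 1, 3, 4, 5, 6, 7, 8, 9])
        with pytest.raises(ValueError, match="ordered"):
            temporal_split((X, y, order))

    def test_test_set_keeps_tail_prevalence(self, rng):
        y = np.zeros(100, dtype=int)
        y[90:] = 1  # all positives in the tail
        X = rng.normal(size=(100, 2))
        (_, ytr), (_, yte) = temporal_split((X, y, np.arange(100)))
        assert yte.mean() == 0.5 and ytr.mean() == 0.0

    def test_feature_table_boundary(self, smoke_season):
        from fwf.datasets import DatasetVariantSpec, build_feature_table, undersample_prematch

        records, calendar, roster, report, _ = smoke_season
        table = undersample_prematch(
            build_feature_table(records, calendar, roster, report,
                                DatasetVariantSpec("baseline_raw")),
            calendar, records,
        )
        train, test = temporal_split(table)
        tr_max = train.features.index.get_level_values("event_index").max()
        te_min = test.features.index.get_level_values("event_index").min()
        assert tr_max <= te_min


class TestSmote:
    def test_balances_classes(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array([1] * 10 + [0] * 50)
        Xb, yb = oversample_smote(X, y, seed=0)
        assert (yb == 1).sum() == (yb == 0).sum() == 50
        # originals preserved as a prefix
        assert np.array_equal(Xb[:60], X)

    def test_synthetics_on_minority_segments(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[5.0, -3.0]] * 8)
        y = np.array([1, 1] + [0] * 8)
        Xb, yb = oversample_smote(X, y, k_neighbors=1, seed=3)
        synth = Xb[10:]
        # every synthetic lies on the segment between (0,0) and (1,1)
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert ((synth >= 0) & (synth <= 1)).all()

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([1] * 8 + [0] * 32)
        a = oversample_smote(X, y, seed=7)
        b = oversample_smote(X, y, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_too_small_minority_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(ValueError, match="smaller k"):
            oversample_smote(X, y, k_neighbors=5)


class TestPcaReduce:
    def test_planar_data_needs_two_components(self, rng):
        basis = rng.normal(size=(2, 5))
        X = rng.normal(size=(50, 2)) @ basis
        _, _, m = pca_reduce(X, X[:5], variance_threshold=0.95)
        assert m == 2

    def test_threshold_one_keeps_rank(self, rng):
        X = rng.normal(size=(30, 4))
        _, _, m = pca_reduce(X, X[:5], variance_threshold=1.0)
        assert m == 4

    def test_eigen_oracle(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(40, 6)) * np.array([5, 3, 2, 1, 0.5, 0.1])
        pca = PCA(svd_solver="full").fit(X)
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(pca.explained_variance_, eig, atol=1e-8)

    def test_train_only_fitting(self, rng):
        """The transform must come from train alone: shifting the test
        set cannot change the projected training data."""
        X_train = rng.normal(size=(30, 4))
        X_test = rng.normal(size=(10, 4))
        Z1, _, _ = pca_reduce(X_train, X_test)
        Z2, _, _ = pca_reduce(X_train, X_test + 100.0)
        assert np.allclose(Z1, Z2)

    def test_bad_threshold(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.normal(size=(10, 2)), rng.normal(size=(2, 2)), 1.5)


class TestComputeMetrics:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        m = compute_metrics(scores, labels)
        assert m.roc_auc == 1.0 and m.gmean == 1.0
        assert m.type1_error == 0.0 and m.type2_error == 0.0

    def test_hand_confusion(self):
        # TP=3, FN=2, TN=100, FP=25
        labels = np.array([1] * 5 + [0] * 125)
        scores = np.array([0.9] * 3 + [0.1] * 2 + [0.1] * 100 + [0.9] * 25)
        m = compute_metrics(scores, labels)
        assert m.type1_error == pytest.approx(0.2)
        assert m.type2_error == pytest.approx(0.4)
        assert m.gmean == pytest.approx(math.sqrt(0.6 * 0.8))
        assert m.accuracy == pytest.approx(103 / 130)

    def test_roc_auc_concordance_oracle(self, rng):
        scores = rng.random(60)
        labels = (rng.random(60) < 0.3).astype(int)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        m = compute_metrics(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
        assert m.roc_auc == pytest.approx(np.mean(pairs))

    def test_single_class_flags_auc_undefined(self):
        m = compute_metrics(np.array([0.1, 0.9]), np.array([0, 0]))
        assert math.isnan(m.roc_auc) and math.isnan(m.pr_auc)
        assert m.type1_error == 0.5  # thresholded metrics still computed


class TestPrBaseline:
    def test_printed_test_set_prevalence(self):
        labels = [1] * 5 + [0] * 147  # 5 positives among 152 samples
        assert round(pr_baseline(labels), 4) == 0.0329

    def test_balanced(self):
        assert pr_baseline([0, 1, 0, 1]) == 0.5

    def test_equals_mean(self, rng):
        for _ in range(10):
            y = (rng.random(50) < 0.3).astype(int)
            if y.sum() == 0:
                y[0] = 1
            assert pr_baseline(y) == y.mean()

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_baseline([0, 0, 0])


class TestConfidenceInterval:
    def test_constant_sequence(self):
        lo, mean, hi = confidence_interval_t([2.0, 2.0, 2.0])
        assert lo == mean == hi == 2.0

    def test_two_point_closed_form(self):
        from scipy import stats

        lo, mean, hi = confidence_interval_t([0.0, 1.0])
        half = stats.t.ppf(0.975, 1) * np.std([0, 1], ddof=1) / math.sqrt(2)
        assert mean == 0.5
        assert hi - mean == pytest.approx(half)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            confidence_interval_t([1.0])


class TestCrossValidate:
    def _data(self, rng, n=60):
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] + rng.normal(scale=0.5, size=n) > 0.8).astype(int)
        if y.sum() < 2:
            y[:2] = 1
        return X, y

    def test_split_count(self, rng):
        X, y = self._data(rng)
        rep = cross_validate(X, y, ModelSpec("LDA"), repeats=10, folds=2, seed=0)
        assert len(rep.val_metrics) == 20
        assert len(rep.train_metrics) == 20

    def test_stratification_within_one_sample(self, rng):
        from sklearn.model_selection import RepeatedStratifiedKFold

        X, y = self._data(rng, n=101)
        splitter = RepeatedStratifiedKFold(n_splits=2, n_repeats=10, random_state=0)
        share = y.sum() / 2
        for _, va in splitter.split(X, y):
            assert abs(y[va].sum() - share) <= 1

    def test_deterministic_given_seed(self, rng):
        X, y = self._data(rng)
        a = cross_validate(X, y, ModelSpec("CART"), repeats=3, folds=2, seed=5)
        b = cross_validate(X, y, ModelSpec("CART"), repeats=3, folds=2, seed=5)
        assert a.val_metrics.equals(b.val_metrics)

    def test_too_few_positives_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.zeros(20, dtype=int)
        y[0] = 1
        with pytest.raises(ValueError, match="positive"):
            cross_validate(X, y, ModelSpec("LDA"), folds=2)

    def test_ci_brackets_mean(self, rng):
        X, y = self._data(rng)
        rep = cross_validate(X, y, ModelSpec("LR"), repeats=5, folds=2, seed=1)
        s = rep.summary("val")
        assert (s["ci_low"] <= s["mean"] + 1e-12).all()
        assert (s["mean"] <= s["ci_high"] + 1e-12).all()

    @pytest.mark.parametrize("family", ["LDA", "LR", "NB", "KNN", "SVM", "CART", "RF", "MLP"])
    def test_all_families_instantiate_and_fit(self, family, rng):
        X, y = self._data(rng, n=40)
        model = make_classifier(ModelSpec(family, seed=0))
        model.fit(X, y)
        assert model.predict(X).shape == (40,)


class TestPermutationTest:
    @staticmethod
    def _metric_of_first_feature(X, y):
        from sklearn.metrics import roc_auc_score

        return roc_auc_score(y, X[:, 0])

    def test_best_case_p(self, rng):
        X = np.linspace(0, 1, 30).reshape(-1, 1)
        y = (X[:, 0] > 0.6).astype(int)
        p, null, obs = permutation_test(self._metric_of_first_feature, X, y,
                                        n_permutations=99, seed=0)
        assert obs == 1.0
        assert p == pytest.approx(1 / 100)

    def test_worst_case_p_is_one(self):
        X = np.linspace(0, 1, 30).reshape(-1, 1)
        y = (X[:, 0] < 0.4).astype(int)  # anti-correlated: every null >= obs
        p, _, _ = permutation_test(self._metric_of_first_feature, X, y,
                                   n_permutations=49, seed=0)
        assert p == 1.0

    def test_invalid_n_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test(self._metric_of_first_feature,
                             rng.normal(size=(10, 1)),
                             np.array([0, 1] * 5), n_permutations=0)


class TestBiasVariance:
    def test_constant_learner(self, rng):
        X_tr = rng.normal(size=(30, 2))
        y_tr = np.array([0] * 25 + [1] * 5)
        X_te = rng.normal(size=(20, 2))
        y_te = np.array([0] * 16 + [1] * 4)
        # KNN with k = n always predicts the training majority (class 0)
        spec = ModelSpec("KNN", (("n_neighbors", 25),))
        loss, bias, var = bias_variance_decompose(spec, X_tr, y_tr, X_te, y_te,
                                                  n_bootstrap=20, seed=0)
        assert var == pytest.approx(0.0, abs=0.02)
        assert bias == pytest.approx(y_te.mean(), abs=0.02)

    def test_terms_in_unit_interval(self, rng):
        X_tr = rng.normal(size=(40, 3))
        y_tr = (X_tr[:, 0] > 0).astype(int)
        X_te = rng.normal(size=(20, 3))
        y_te = (X_te[:, 0] > 0).astype(int)
        loss, bias, var = bias_variance_decompose(ModelSpec("CART"), X_tr, y_tr,
                                                  X_te, y_te, n_bootstrap=30, seed=1)
        for t in (loss, bias, var):
            assert 0.0 <= t <= 1.0
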