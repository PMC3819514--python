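"""Tests for normalization, t-test selection, classifiers and true error."""

import numpy as np
import pytest
from scipy import stats

from countsim import (ClassifierSpec, KNNClassifier, LDAClassifier, Normalizer,
                      ParameterError, RBFSVMClassifier, select_top_features,
                      t_scores, train_classifier, true_error)


class TestNormalizer:
    def test_training_data_becomes_zero_mean_unit_sd(self, rng):
        X = rng.normal(3, 2, (50, 6))
        norm = Normalizer.fit(X)
        Z = norm.transform(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1)

    def test_constant_feature_maps_to_zero_everywhere(self, rng):
        X = np.column_stack([np.full(20, 7.0), rng.normal(size=20)])
        norm = Normalizer.fit(X)
        test = np.column_stack([rng.normal(size=10), rng.normal(size=10)])
        assert np.all(norm.transform(X)[:, 0] == 0)
        assert np.all(norm.transform(test)[:, 0] == 0)

    def test_test_shift_scales_by_training_sd(self, rng):
        # affine algebra: shifting a test feature by +c shifts its z-scores
        # by c / sd_train
        X = rng.normal(size=(40, 3))
        norm = Normalizer.fit(X)
        T = rng.normal(size=(15, 3))
        shifted = T.copy()
        shifted[:, 1] += 2.5
        delta = norm.transform(shifted)[:, 1] - norm.transform(T)[:, 1]
        assert np.allclose(delta, 2.5 / X[:, 1].std())


class TestTScores:
    def test_hand_computed_pooled_t(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        # pooled two-sample t: (5-2)/sqrt(1*(1/3+1/3))
        assert t_scores(X, y)[0] == pytest.approx(3 / np.sqrt(2 / 3))

    def test_matches_scipy_on_random_and_count_scale_data(self, rng):
        X = np.column_stack([rng.normal(size=80),
                             rng.poisson(1e5, 80).astype(float),
                             rng.normal(5, 3, 80)])
        y = (rng.random(80) < 0.5).astype(int)
        ours = t_scores(X, y)
        ref = stats.ttest_ind(X[y == 1], X[y == 0], equal_var=True).statistic
        assert np.allclose(ours, ref, rtol=1e-8)

    def test_rank_invariant_under_affine_transforms(self, rng):
        X = rng.normal(size=(60, 30))
        y = np.repeat([0, 1], 30)
        scale = rng.uniform(0.1, 10, 30)
        shift = rng.normal(0, 5, 30)
        a = np.abs(t_scores(X, y))
        b = np.abs(t_scores(X * scale + shift, y))
        assert np.array_equal(np.argsort(-a, kind="stable"),
                              np.argsort(-b, kind="stable"))
        assert np.array_equal(select_top_features(a, 5),
                              select_top_features(b, 5))

    def test_null_distribution(self, rng):
        X = rng.normal(size=(30, 10000))
        y = np.repeat([0, 1], 15)
        t = t_scores(X, y)
        assert stats.kstest(t, stats.t(df=28).cdf).pvalue > 1e-3

    def test_zero_variance_conventions(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 1.0], [2.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        t = t_scores(X, y)
        assert t[0] == np.inf      # means differ, no within-class spread
        assert t[1] == 0.0         # fully constant feature

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            t_scores(np.ones((4, 2)), np.zeros(4))


class TestSelectTopFeatures:
    def test_largest_absolute_scores_win(self):
        assert np.array_equal(select_top_features(np.array([0.1, 5, 3]), 2), [1, 2])
        assert np.array_equal(select_top_features(np.array([0.1, -5, 3]), 2), [1, 2])

    def test_ties_break_to_lowest_index(self):
        assert np.array_equal(select_top_features(np.ones(6), 3), [0, 1, 2])

    def test_d_equals_everything(self, rng):
        s = rng.normal(size=8)
        assert np.array_equal(select_top_features(s, 8), np.arange(8))

    def test_d_too_large_rejected(self):
        with pytest.raises(ParameterError):
            select_top_features(np.ones(3), 4)


class TestLDA:
    def test_nearest_mean_with_identity_covariance(self, rng):
        # spherical classes -> LDA reduces to nearest centroid
        X = np.vstack([rng.normal(0, 1, (200, 2)), rng.normal(1, 1, (200, 2))])
        y = np.repeat([0, 1], 200)
        clf = LDAClassifier().fit(X, y)
        assert clf.predict([[0.05, -0.1]])[0] == 0
        assert clf.predict([[1.1, 0.9]])[0] == 1

    def test_boundary_point_assigned_class_one(self):
        # equidistant point: the printed "<=" convention gives class 1
        X = np.array([[0.0, 0], [0, 0.2], [-0.2, 0],
                      [1.0, 1], [1, 0.8], [1.2, 1]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = LDAClassifier().fit(X, y)
        mid = (clf.mu0_ + clf.mu1_) / 2
        assert clf.predict([mid])[0] == 1

    def test_matches_sklearn_off_boundary(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = np.vstack([rng.normal(0, 1, (60, 4)), rng.normal(0.8, 1.2, (60, 4))])
        y = np.repeat([0, 1], 60)
        ours = LDAClassifier().fit(X, y)
        ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        T = rng.normal(0.4, 1.5, (300, 4))
        assert np.mean(ours.predict(T) == ref.predict(T)) > 0.97

    def test_large_sample_error_hits_gaussian_limit(self):
        # equal-covariance Gaussians: true error -> Phi(-delta/2) with
        # delta^2 = (m1-m0)^2 / sigma^2 * 1' Sigma^{-1} 1
        from countsim import ModelConfig, sample_expression
        cfg = ModelConfig(D=110, rho=0.8, D_gm=10, c=2, D_hm=50, D_hv=0, D_lv=0)
        rng = np.random.default_rng(50)
        tr = sample_expression(cfg, 10000, rng, feature_subset=np.arange(10))
        clf = LDAClassifier().fit(tr.X, tr.y)
        te = sample_expression(cfg, 200000, np.random.default_rng(51),
                               stratified=True, annotation=tr.annotation,
                               feature_subset=np.arange(10))
        err = np.mean(clf.predict(te.X) != te.y)
        delta2 = 2 * (5 / (1 + 4 * 0.8)) / 0.36
        bayes = stats.norm.cdf(-np.sqrt(delta2) / 2)
        assert bayes == pytest.approx(0.0992, abs=3e-4)
        assert abs(err - bayes) < 0.01

    def test_ridge_fallback_on_singular_covariance(self):
        X = np.array([[0.0, 0], [0, 0], [0, 0], [1, 1], [1, 1], [1, 1]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = LDAClassifier().fit(X, y)  # zero pooled covariance
        assert clf.predict([[0.9, 0.9]])[0] == 1


class Test3NN:
    def test_majority_of_three(self):
        X = np.array([[0.0, 0], [0.1, 0], [1, 1]])
        y = np.array([0, 0, 1])
        clf = KNNClassifier().fit(X, y)
        assert clf.predict([[0.0, 0.05]])[0] == 0

    def test_exact_triplicate_match(self):
        X = np.array([[2.0, 2], [2, 2], [2, 2], [0, 0]])
        y = np.array([1, 1, 1, 0])
        assert KNNClassifier().fit(X, y).predict([[2, 2]])[0] == 1

    def test_distance_ties_break_to_lowest_index(self):
        # four equidistant neighbours; the first three (indices 0,1,2) vote
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        y = np.array([1, 1, 0, 0])
        assert KNNClassifier().fit(X, y).predict([[0.0, 0]])[0] == 1

    def test_matches_sklearn_without_ties(self, rng):
        from sklearn.neighbors import KNeighborsClassifier
        X = rng.normal(size=(60, 3))
        y = (rng.random(60) < 0.5).astype(int)
        T = rng.normal(size=(100, 3))
        ours = KNNClassifier().fit(X, y).predict(T)
        ref = KNeighborsClassifier(n_neighbors=3).fit(X, y).predict(T)
        assert np.array_equal(ours, ref)

    def test_well_separated_classes_near_zero_error(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(10, 1, (50, 2))])
        y = np.repeat([0, 1], 50)
        T = np.vstack([rng.normal(0, 1, (500, 2)), rng.normal(10, 1, (500, 2))])
        ty = np.repeat([0, 1], 500)
        err = np.mean(KNNClassifier().fit(X, y).predict(T) != ty)
        assert err < 0.01

    def test_too_few_training_points_rejected(self):
        with pytest.raises(ParameterError):
            KNNClassifier().fit(np.ones((2, 2)), np.array([0, 1]))


class TestRBFSVM:
    def test_separable_problem_zero_training_error(self):
        X = np.array([[0.0, 0], [1, 1]])
        y = np.array([0, 1])
        clf = RBFSVMClassifier().fit(X, y)
        assert np.array_equal(clf.predict(X), y)

    def test_xor_pattern_separated_nonlinearly(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([0, 0, 1, 1])
        clf = RBFSVMClassifier(C=100.0, gamma=2.0).fit(X, y)
        assert np.array_equal(clf.predict(X), y)

    def test_label_flip_symmetry(self, rng):
        X = rng.normal(size=(40, 2))
        y = (rng.random(40) < 0.5).astype(int)
        T = rng.normal(size=(50, 2))
        a = RBFSVMClassifier().fit(X, y).predict(T)
        b = RBFSVMClassifier().fit(X, 1 - y).predict(T)
        assert np.array_equal(a, 1 - b)


class TestTrainedClassifierAndTrueError:
    def _toy(self, rng, n=60, D=30):
        X = rng.normal(size=(n, D))
        X[:, 4] += np.repeat([0, 3], n // 2)
        y = np.repeat([0, 1], n // 2)
        return X, y

    def test_selection_feeds_the_rule(self, rng):
        X, y = self._toy(rng)
        clf = train_classifier(X, y, ClassifierSpec(rule="LDA", d=1))
        assert 4 in clf.feature_idx
        T, ty = self._toy(rng, n=200)
        assert true_error(clf, T, ty) < 0.1

    def test_constant_classifier_scores_half_on_balanced_test(self, rng):
        X, y = self._toy(rng)
        clf = train_classifier(X, y, ClassifierSpec(rule="LDA", d=1))
        T = np.full((100, 30), -50.0)  # far on the class-0 side
        ty = np.repeat([0, 1], 50)
        assert true_error(clf, T, ty) == pytest.approx(0.5)

    def test_perfect_classifier_scores_zero(self, rng):
        X, y = self._toy(rng)
        clf = train_classifier(X, y, ClassifierSpec(rule="3NN", d=1))
        T, ty = self._toy(rng, n=100)
        T[:, 4] += np.where(ty == 1, 5, -5)
        assert true_error(clf, T, ty) == 0.0

    def test_label_randomised_test_near_half(self, rng):
        X, y = self._toy(rng)
        clf = train_classifier(X, y, ClassifierSpec(rule="LDA", d=2))
        T, _ = self._toy(rng, n=2000)
        ty = (rng.random(2000) < 0.5).astype(int)
        assert abs(true_error(clf, T, ty) - 0.5) < 3 * 0.5 / np.sqrt(2000)

    def test_none_global_uses_given_markers(self, rng):
        X, y = self._toy(rng)
        spec = ClassifierSpec(rule="LDA", d=2, selection="NONE_GLOBAL")
        clf = train_classifier(X, y, spec, global_idx=np.array([4, 7]))
        assert np.array_equal(clf.feature_idx, [4, 7])

    def test_column_mismatch_rejected(self, rng):
        X, y = self._toy(rng)
        clf = train_classifier(X, y, ClassifierSpec(rule="LDA", d=2))
        with pytest.raises(ParameterError):
            true_error(clf, X[:, :2], y, columns=np.array([0, 1000]))

    def test_spec_validation(self):
        with pytest.raises(ParameterError):
            ClassifierSpec(rule="QDA")
        with pytest.raises(ParameterError):
            ClassifierSpec(selection="RANDOM")


class TestMetadata:
    def test_trained_classifier_metadata_serialises(self, rng):
        import json
        X = rng.normal(size=(40, 12))
        y = np.repeat([0, 1], 20)
        clf = train_classifier(X, y, ClassifierSpec(rule="RBF_SVM", d=3))
        meta = json.loads(json.dumps(clf.metadata()))
        assert meta["rule"] == "RBF_SVM"
        assert len(meta["selected_features"]) == 3
        assert meta["gamma"] == pytest.approx(1 / 3)
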