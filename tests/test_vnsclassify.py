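"""Gaussian naive Bayes, stratified CV, balanced repeated CV and the metrics."""

import numpy as np
import pandas as pd
import pytest

from megnet_vns.vnsclassify import (
    CLASSES,
    GaussianNBModel,
    auc_one_vs_rest,
    balanced_repeated_cv,
    fit_gnb,
    metrics_from_confusion,
    predict_gnb,
    select_features,
    stratified_kfold_predict,
)


class TestGnb:
    def test_symmetric_two_class_boundary_at_zero(self):
        model = GaussianNBModel(
            classes=np.array(["a", "b"]),
            priors=np.array([0.5, 0.5]),
            means=np.array([[-1.0], [1.0]]),
            variances=np.array([[1.0], [1.0]]),
        )
        post, labels = predict_gnb(model, [[0.0]])
        np.testing.assert_allclose(post[0], [0.5, 0.5])
        assert labels[0] == "a"  # lexicographic tie-break

    def test_equal_class_parameters_return_priors(self):
        model = GaussianNBModel(
            classes=np.array(["a", "b", "c"]),
            priors=np.array([0.2, 0.3, 0.5]),
            means=np.zeros((3, 2)),
            variances=np.ones((3, 2)),
        )
        post, _ = predict_gnb(model, [[0.3, -1.2], [5.0, 5.0]])
        np.testing.assert_allclose(post, [[0.2, 0.3, 0.5]] * 2)

    def test_hand_set_parameters_match_bayes_arithmetic(self):
        from scipy.stats import norm

        model = GaussianNBModel(
            classes=np.array(["a", "b"]),
            priors=np.array([0.3, 0.7]),
            means=np.array([[0.0], [2.0]]),
            variances=np.array([[1.0], [4.0]]),
        )
        for x in (-1.0, 0.5, 3.0):
            post, _ = predict_gnb(model, [[x]])
            la = 0.3 * norm.pdf(x, 0, 1)
            lb = 0.7 * norm.pdf(x, 2, 2)
            np.testing.assert_allclose(post[0], [la, lb] / (la + lb), atol=1e-12)

    def test_fit_recovers_empirical_moments(self, rng):
        x = np.concatenate([rng.normal(0, 1, (50, 2)), rng.normal(3, 2, (70, 2))])
        y = np.array(["a"] * 50 + ["b"] * 70)
        model = fit_gnb(x, y)
        np.testing.assert_allclose(model.priors, [50 / 120, 70 / 120])
        np.testing.assert_allclose(model.means[0], x[:50].mean(axis=0))
        np.testing.assert_allclose(model.variances[1], x[50:].var(axis=0))

    def test_agrees_with_sklearn_gaussian_nb(self, rng):
        from sklearn.naive_bayes import GaussianNB

        x = rng.normal(size=(60, 3))
        y = rng.choice(["u", "v", "w"], size=60)
        model = fit_gnb(x, y)
        post, labels = predict_gnb(model, x)
        ref = GaussianNB().fit(x, y)
        np.testing.assert_allclose(post, ref.predict_proba(x), atol=1e-6)
        assert np.array_equal(labels, ref.predict(x))

    def test_variance_floor_keeps_degenerate_feature_finite(self):
        x = np.array([[1.0, 5.0], [1.0, 6.0], [1.0, 7.0], [1.0, 8.0]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_gnb(x, y)
        post, _ = predict_gnb(model, [[1.0, 6.5]])
        assert np.isfinite(post).all()

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_gnb(rng.normal(size=(10, 2)), np.array(["a", "b"] * 5))
        with pytest.raises(ValueError):
            predict_gnb(model, [[1.0, 2.0, 3.0]])


class TestStratifiedKfold:
    def test_each_subject_tested_once_at_clinical_sizes(self, rng):
        x = rng.normal(size=(37, 2))
        y = np.array(["NR"] * 9 + ["R"] * 14 + ["C"] * 14)
        post, pred, classes = stratified_kfold_predict(x, y, k=10, seed=1)
        assert post.shape == (37, 3)
        np.testing.assert_allclose(post.sum(axis=1), 1.0)
        assert set(pred) <= set(CLASSES)

    def test_leave_one_out_reproducible(self, rng):
        x = rng.normal(size=(12, 2))
        y = np.array(["a", "b"] * 6)
        r1 = stratified_kfold_predict(x, y, k=12, seed=4)
        r2 = stratified_kfold_predict(x, y, k=12, seed=4)
        np.testing.assert_array_equal(r1[0], r2[0])
        np.testing.assert_array_equal(r1[1], r2[1])

    def test_perfectly_separated_classes_score_perfectly(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, (12, 1)), rng.normal(10, 0.1, (12, 1))])
        y = np.array(["a"] * 12 + ["b"] * 12)
        _, pred, _ = stratified_kfold_predict(x, y, k=6, seed=0)
        assert np.array_equal(pred, y)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            stratified_kfold_predict(rng.normal(size=(5, 1)), np.array(list("aabbb")), k=6)

    def test_fold_sizes_balanced(self, rng):
        y = np.array(["NR"] * 9 + ["R"] * 14 + ["C"] * 14)
        from megnet_vns.vnsclassify import _stratified_folds

        folds = _stratified_folds(y, 10, rng)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 1


class TestMetrics:
    def test_printed_confusion_row_arithmetic(self):
        """One-vs-rest metrics from a 3x3 confusion with rows 9/14/14."""
        conf = np.array([[5, 4, 0], [2, 11, 1], [0, 1, 13]])
        df = metrics_from_confusion(conf)
        assert df.loc["NR", "sensitivity"] == pytest.approx(5 / 9)
        assert round(df.loc["NR", "sensitivity"], 2) == 0.56
        # weighted row is the class-size weighted mean of per-class values
        expected = np.average(df.loc[list(CLASSES), "sensitivity"], weights=[9, 14, 14])
        assert df.loc["weighted", "sensitivity"] == pytest.approx(expected)

    def test_identity_confusion_all_ones(self):
        df = metrics_from_confusion(np.diag([9, 14, 14]))
        assert (df[["sensitivity", "specificity", "ppv", "accuracy"]] == 1.0).all().all()

    def test_never_predicted_class_has_nan_ppv(self):
        conf = np.array([[0, 5, 4], [0, 10, 4], [0, 2, 12]])
        df = metrics_from_confusion(conf)
        assert np.isnan(df.loc["NR", "ppv"])
        assert np.isfinite(df.loc["weighted", "ppv"])

    def test_invalid_confusion_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.ones((2, 2)))


class TestAuc:
    def test_perfect_ordering_gives_one(self):
        post = np.array([[0.9, 0.05, 0.05], [0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.2, 0.1, 0.7]])
        labels = np.array(["NR", "NR", "R", "C"])
        aucs = auc_one_vs_rest(post, labels, np.array(["NR", "R", "C"]))
        assert aucs["NR"] == 1.0

    def test_hand_example_with_tie_matches_u_statistic(self):
        # scores for class 'a': positives {0.8, 0.5}, negatives {0.5, 0.2}
        # concordant pairs: (0.8,0.5),(0.8,0.2),(0.5,0.2)=3; tie (0.5,0.5)=0.5
        post = np.array([[0.8, 0.2], [0.5, 0.5], [0.5, 0.5], [0.2, 0.8]])
        labels = np.array(["a", "a", "b", "b"])
        aucs = auc_one_vs_rest(post, labels, np.array(["a", "b"]))
        assert aucs["a"] == pytest.approx(3.5 / 4)

    def test_label_independent_scores_near_half(self, rng):
        post = rng.dirichlet(np.ones(3), size=400)
        labels = rng.choice(["NR", "R", "C"], size=400)
        aucs = auc_one_vs_rest(post, labels, np.array(["C", "NR", "R"]))
        for v in aucs.values():
            assert abs(v - 0.5) < 0.08


class TestBalancedRepeatedCv:
    def _cohort(self, rng, n_controls=30, separated=False):
        if separated:
            centers = {"NR": (-6, 0), "R": (0, 6), "C": (6, -6)}
            scale = 0.3
        else:
            centers = {"NR": (0, 0), "R": (0, 0), "C": (0, 0)}
            scale = 1.0
        xs, ys = [], []
        for label, n in (("NR", 9), ("R", 14), ("C", n_controls)):
            xs.append(rng.normal(centers[label], scale, size=(n, 2)))
            ys += [label] * n
        return np.vstack(xs), np.array(ys)

    def test_confusion_rows_sum_to_class_sizes(self, rng):
        x, y = self._cohort(rng)
        rep = balanced_repeated_cv(x, y, n_reps=20, seed=3)
        np.testing.assert_allclose(rep.confusion.sum(axis=1), [9, 14, 14])

    def test_separable_features_reach_high_accuracy(self, rng):
        x, y = self._cohort(rng, separated=True)
        rep = balanced_repeated_cv(x, y, n_reps=20, seed=3)
        assert rep.overall_accuracy > 0.95
        assert rep.per_class.loc["weighted", "auc"] > 0.98

    def test_same_seed_fully_reproducible(self, rng):
        x, y = self._cohort(rng)
        r1 = balanced_repeated_cv(x, y, n_reps=10, seed=11)
        r2 = balanced_repeated_cv(x, y, n_reps=10, seed=11)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        pd.testing.assert_frame_equal(r1.per_class, r2.per_class)

    def test_too_few_controls_rejected(self, rng):
        x, y = self._cohort(rng, n_controls=10)
        with pytest.raises(ValueError):
            balanced_repeated_cv(x, y, n_reps=2, n_controls_drawn=14)


class TestSelectFeatures:
    def test_band_menus(self):
        df = pd.DataFrame(
            np.arange(12).reshape(2, 6),
            columns=[
                f"{m}_{b}"
                for b in ("theta", "alpha", "beta")
                for m in ("transitivity", "modularity")
            ],
        )
        x, names = select_features(df, "theta")
        assert names == ["transitivity_theta", "modularity_theta"]
        x6, names6 = select_features(df, "all")
        assert x6.shape == (2, 6)
        with pytest.raises(KeyError):
            select_features(df.drop(columns=["modularity_beta"]), "all")
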