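import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from canopyspec import synth
from canopyspec.models import (
    SplitSpec,
    allocate_split_counts,
    evaluate,
    fit_lda,
    fit_plsda,
    fit_svm_ovr,
    load_model,
    plsda_confident,
    predict_plsda,
    save_model,
    select_n_lv,
    stratified_split,
)

RNG = np.random.default_rng(0)


class TestSplitting:
    @pytest.mark.parametrize("n,expected", [
        (3450, (2070, 690, 690)),
        (6450, (3870, 1290, 1290)),
        (6558, (3935, 1312, 1311)),
        (10, (6, 2, 2)),
    ])
    def test_largest_remainder_counts(self, n, expected):
        assert allocate_split_counts(n) == expected

    def test_split_is_disjoint_exhaustive_and_proportional(self):
        t = synth.sample_spectra_table(
            {"control": 37, "early": 41, "severe": 29}, seed=1)
        out = stratified_split(t, SplitSpec(seed=5))
        assert set(out.split) == {"cal", "val", "test"}
        for cat in ("control", "early", "severe"):
            m = out.labels == cat
            n = m.sum()
            counts = [(out.split[m] == s).sum() for s in ("cal", "val", "test")]
            assert sum(counts) == n
            for c, f in zip(counts, (0.6, 0.2, 0.2)):
                assert abs(c - f * n) < 1     # within one sample of target

    def test_split_deterministic(self):
        t = synth.sample_spectra_table({"control": 20, "severe": 20}, seed=2)
        a = stratified_split(t, SplitSpec(seed=7))
        b = stratified_split(t, SplitSpec(seed=7))
        assert np.array_equal(a.split, b.split)

    def test_small_category_rejected(self):
        t = synth.sample_spectra_table({"control": 4, "severe": 20}, seed=3)
        with pytest.raises(ValueError, match="fewer than 5"):
            stratified_split(t)


class TestPLSDA:
    def test_full_rank_beta_equals_least_squares(self):
        """With as many latent variables as the rank, PLS-DA reproduces
        the multivariate least-squares solution."""
        X = RNG.normal(size=(30, 5))
        y = np.array(["a", "b", "c"] * 10)
        model = fit_plsda(X, y, n_lv=5)
        Y = np.array([[1.0 if lab == c else 0.0
                       for c in model.categories] for lab in y])
        Xc = X - X.mean(axis=0)
        beta_ols = np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)[0]
        assert np.allclose(model.beta, beta_ols, atol=1e-8)

    def test_separable_two_class_perfect_with_one_lv(self):
        X = RNG.normal(size=(40, 6))
        y = np.array(["neg", "pos"] * 20)
        X[:, 0] += np.where(y == "pos", 5.0, -5.0)
        model = fit_plsda(X, y, n_lv=1)
        _, pred = predict_plsda(model, X)
        assert (pred == y).mean() == 1.0

    def test_prediction_scores_and_confidence(self):
        model = fit_plsda(RNG.normal(size=(12, 4)),
                          np.array(["a", "b"] * 6), n_lv=2)
        model.beta = np.zeros((4, 2))
        model.intercepts = np.array([0.0, 0.0])
        scores = np.array([[0.9, 0.1], [0.4, 0.35]])
        conf = plsda_confident(model, scores)
        assert conf.tolist() == [True, False]
        assert np.argmax(scores, axis=1).tolist() == [0, 0]

    def test_centroid_sample_is_confident(self):
        t = synth.sample_spectra_table(
            {c: 30 for c in ("control", "early", "severe")},
            seed=4, noise_sd=0.0, scatter_slope_range=(1.0, 1.0),
            scatter_offset_range=(0.0, 0.0))
        model = fit_plsda(t.X, t.labels, n_lv=2)
        centroid = t.X[t.labels == "severe"].mean(axis=0)[None, :]
        scores, pred = predict_plsda(model, centroid)
        assert pred[0] == "severe"
        assert plsda_confident(model, scores)[0]

    def test_band_mismatch_rejected(self):
        model = fit_plsda(RNG.normal(size=(12, 4)),
                          np.array(["a", "b"] * 6), n_lv=2)
        with pytest.raises(ValueError, match="band-count"):
            predict_plsda(model, RNG.normal(size=(3, 7)))

    def test_lv_policy_prefers_ten_on_plateau(self):
        """When validation accuracy saturates below 10 LVs the policy
        still returns the conventional 10-LV model."""
        X = RNG.normal(size=(120, 20))
        y = np.array(["a", "b", "c"] * 40)
        X[:, 0] += np.where(y == "a", 6.0, 0.0)
        X[:, 1] += np.where(y == "b", 6.0, 0.0)
        Xv = RNG.normal(size=(60, 20))
        yv = np.array(["a", "b", "c"] * 20)
        Xv[:, 0] += np.where(yv == "a", 6.0, 0.0)
        Xv[:, 1] += np.where(yv == "b", 6.0, 0.0)
        assert select_n_lv(X, y, Xv, yv) == 10

    def test_rank_deficient_reduces_lvs_with_warning(self):
        X = np.tile(RNG.normal(size=(20, 2)), (1, 3))   # rank 2, 6 cols
        y = np.array(["a", "b"] * 10)
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = fit_plsda(X, y, n_lv=5)
        assert model.n_lv == 2


class TestLDA:
    def test_two_spherical_gaussians_bisector_boundary(self):
        """With identity covariance and equal priors the decision boundary
        is exactly the perpendicular bisector of the class means."""
        from canopyspec.models import LDAModel
        means = np.array([[0.0, 0.0], [4.0, 0.0]])
        model = LDAModel(["a", "b"], means, np.eye(2),
                         np.array([0.5, 0.5]), shrinkage=0.0)
        probe = np.array([[2.0, -3.0], [2.0, 0.0], [2.0, 3.0]])
        d = model.decision_values(probe)
        assert np.allclose(d[:, 0], d[:, 1])
        assert model.predict(np.array([[1.9, 5.0]]))[0] == "a"
        assert model.predict(np.array([[2.1, -5.0]]))[0] == "b"
        # and the fitted version recovers the same boundary approximately
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(means[0], 1.0, (200, 2)),
                       rng.normal(means[1], 1.0, (200, 2))])
        y = np.array(["a"] * 200 + ["b"] * 200)
        fitted = fit_lda(X, y, shrinkages=(0.01,))
        assert fitted.predict(np.array([[0.0, 0.0]]))[0] == "a"
        assert fitted.predict(np.array([[4.0, 0.0]]))[0] == "b"

    def test_identical_means_gives_chance_accuracy(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 4))
        y = np.array(["a", "b", "c"] * 100)
        model = fit_lda(X, y, shrinkages=(0.1,), seed=0)
        acc = (model.predict(X) == y).mean()
        assert abs(acc - 1 / 3) < 0.12

    def test_discriminants_match_direct_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        y = np.array(["a", "b", "c"] * 4)
        model = fit_lda(X, y, shrinkages=(0.1,), folds=2)
        Sinv = np.linalg.inv(model.covariance)
        for x in X[:5]:
            for i, c in enumerate(model.categories):
                mu = model.means[i]
                delta = x @ Sinv @ mu - 0.5 * mu @ Sinv @ mu + np.log(
                    model.priors[i])
                assert model.decision_values(x[None, :])[0, i] == (
                    pytest.approx(delta))

    def test_agreement_with_reference_implementation(self):
        """Cross-check predictions against sklearn's shrinkage LDA."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(90, 6))
        y = np.array(["a", "b", "c"] * 30)
        X[:, 0] += np.where(y == "a", 2.0, 0.0)
        X[:, 1] += np.where(y == "b", 2.0, 0.0)
        model = fit_lda(X, y, shrinkages=(0.1,))
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.1).fit(X, y)
        agree = (model.predict(X) == sk.predict(X)).mean()
        assert agree > 0.97


class TestSVM:
    def test_separable_data_perfect_calibration_accuracy(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        y = np.array(["neg", "pos"] * 30)
        X[:, 0] += np.where(y == "pos", 6.0, -6.0)
        model = fit_svm_ovr(X, y, Cs=(100.0,), gamma_factors=(1.0,))
        assert (model.predict(X) == y).mean() == 1.0

    def test_decision_values_match_kernel_sum_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(45, 4))
        y = np.array(["a", "b", "c"] * 15)
        X[:, 0] += np.where(y == "a", 3.0, 0.0)
        model = fit_svm_ovr(X, y, Cs=(1.0, 10.0), gamma_factors=(1.0,))
        probe = rng.normal(size=(7, 4))
        d = model.decision_values(probe)
        for ci in range(3):
            sv = model.support_vectors[ci]
            ay = model.dual_coef[ci]
            for r, x in enumerate(probe):
                ksum = sum(a * np.exp(-model.gamma *
                                      np.sum((x - s) ** 2))
                           for a, s in zip(ay, sv)) + model.bias[ci]
                assert d[r, ci] == pytest.approx(ksum, rel=1e-8)

    def test_empty_rest_class_rejected(self):
        X = RNG.normal(size=(10, 3))
        y = np.array(["only"] * 10)
        with pytest.raises(ValueError):
            fit_svm_ovr(X, y, Cs=(1.0,), gamma_factors=(1.0,), folds=2)


class TestEvaluate:
    def test_perfect_confusion(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0
        assert rep.precision_macro == rep.recall_macro == rep.f1_macro == 1.0
        assert np.array_equal(rep.confusion, [[5, 0], [0, 5]])

    def test_binary_arithmetic(self):
        # TP=3 FN=1 FP=2 TN=4 for the positive category
        y_true = np.array(["p"] * 4 + ["n"] * 6)
        y_pred = np.array(["p", "p", "p", "n", "p", "p", "n", "n", "n", "n"])
        rep = evaluate(y_true, y_pred)
        pc = rep.per_category["p"]
        assert pc["precision"] == pytest.approx(0.6)
        assert pc["recall"] == pytest.approx(0.75)
        assert pc["f1"] == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_macro_f1_matches_harmonic_mean_oracle(self):
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 1, 9]])
        cats = ["x", "y", "z"]
        y_true = np.repeat(cats, 10)
        y_pred = np.concatenate([np.repeat(cats, cm[i])
                                 for i in range(3)])
        rep = evaluate(y_true, y_pred, categories=cats)
        f1s = []
        for i in range(3):
            p = cm[i, i] / cm[:, i].sum()
            r = cm[i, i] / cm[i].sum()
            f1s.append(2 * p * r / (p + r))
        assert rep.f1_macro == pytest.approx(np.mean(f1s))

    def test_never_predicted_category_flagged(self):
        y_true = np.array(["a", "a", "b", "b"])
        y_pred = np.array(["a", "a", "a", "a"])
        rep = evaluate(y_true, y_pred)
        assert rep.undefined_precision == ["b"]
        assert rep.per_category["b"]["precision"] == 0.0

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(7)
        y = rng.choice(["a", "b"], size=1000)
        scores = rng.uniform(size=(1000, 2))
        pred = np.where(scores[:, 0] > scores[:, 1], "a", "b")
        rep = evaluate(y, pred, scores=scores, categories=["a", "b"])
        assert abs(rep.auc_macro - 0.5) < 0.05


class TestSerialization:
    def test_plsda_roundtrip(self, tmp_path, snv_splits):
        Xc, yc, Xv, *_ = snv_splits
        model = fit_plsda(Xc, yc, n_lv=5, preprocess=snv_splits[6])
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        s1, p1 = predict_plsda(model, Xv)
        s2, p2 = predict_plsda(back, Xv)
        assert np.allclose(s1, s2)
        assert np.array_equal(p1, p2)

    def test_lda_and_svm_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 4))
        y = np.array(["a", "b", "c"] * 20)
        X[:, 0] += np.where(y == "a", 3.0, 0.0)
        for fit in (lambda: fit_lda(X, y, shrinkages=(0.1,)),
                    lambda: fit_svm_ovr(X, y, Cs=(1.0,),
                                        gamma_factors=(1.0,))):
            model = fit()
            save_model(model, tmp_path / "m.json")
            back = load_model(tmp_path / "m.json")
            assert np.array_equal(model.predict(X), back.predict(X))
            assert np.allclose(model.decision_values(X),
                               back.decision_values(X))
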