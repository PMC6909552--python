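"""October normalization, PCA, the softmax stage model, and evaluation."""

import numpy as np
import pandas as pd
import pytest

import budphase as bp
from budphase.containers import STAGES, BudphaseError
from budphase.stagemodel import (penalized_nll, softmax_gradient_norm,
                                 _fit_softmax)


def _panel_and_meta():
    cols = ["oct_1", "oct_2", "dec_1"]
    panel = pd.DataFrame([[4.0, 4.0, 10.0], [2.0, 2.0, 1.0]],
                         index=["g1", "g2"], columns=cols)
    meta = bp.validate_metadata(pd.DataFrame({
        "sample_id": cols, "cultivar": "cv", "tree": ["t1", "t2", "t1"],
        "date": ["2015-10-15", "2015-10-15", "2015-12-15"]}))
    return panel, meta


class TestOctoberNormalize:
    def test_reference_maps_to_one(self):
        panel, meta = _panel_and_meta()
        out = bp.october_normalize(panel, meta)
        np.testing.assert_allclose(out[["oct_1", "oct_2"]].to_numpy(), 1.0)

    def test_division_value(self):
        panel, meta = _panel_and_meta()
        out = bp.october_normalize(panel, meta)
        assert out.loc["g1", "dec_1"] == pytest.approx(2.5)
        assert out.loc["g2", "dec_1"] == pytest.approx(0.5)

    def test_linearity(self):
        panel, meta = _panel_and_meta()
        out1 = bp.october_normalize(panel, meta)
        panel2 = panel.copy()
        panel2["dec_1"] *= 2.0
        out2 = bp.october_normalize(panel2, meta)
        np.testing.assert_allclose(out2["dec_1"], 2 * out1["dec_1"])

    def test_zero_reference_names_gene_and_cultivar(self):
        panel, meta = _panel_and_meta()
        panel.loc["g1", ["oct_1", "oct_2"]] = 0.0
        with pytest.raises(BudphaseError, match="g1.*cv"):
            bp.october_normalize(panel, meta)

    def test_missing_october_rejected(self):
        panel, meta = _panel_and_meta()
        meta["date"] = pd.Timestamp("2015-12-15")
        with pytest.raises(BudphaseError, match="reference"):
            bp.october_normalize(panel, meta)


class TestPCA:
    def test_line_gives_full_first_component(self):
        t = np.linspace(0, 1, 8)
        X = pd.DataFrame(np.c_[t, 2 * t, -t], columns=list("abc"))
        pca = bp.fit_pca(X)
        assert pca.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_center_projects_to_origin(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(10, 4)))
        pca = bp.fit_pca(X)
        center_row = pd.DataFrame([pca.center], columns=X.columns)
        np.testing.assert_allclose(bp.project(pca, center_row), 0, atol=1e-9)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(12, 5)))
        pca = bp.fit_pca(X)
        centered = X.to_numpy() - X.to_numpy().mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        for j in range(2):
            dot = abs(np.dot(pca.loadings[:, j], vt[j]))
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_training_scores_reproduced(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(9, 4)))
        pca = bp.fit_pca(X)
        s1 = bp.project(pca, X)
        s2 = bp.project(pca, X.copy())
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_rank_deficient_rejected(self):
        X = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(BudphaseError):
            bp.fit_pca(X)

    def test_feature_mismatch_lists_missing(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=["m1", "m2", "m3"])
        pca = bp.fit_pca(X)
        with pytest.raises(BudphaseError, match="m3"):
            bp.project(pca, X[["m1", "m2"]])


def _toy_two_class(n=30, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([-gap / 2, 0], 0.5, size=(n, 2))
    b = rng.normal([gap / 2, 0], 0.5, size=(n, 2))
    X = np.vstack([a, b])
    y = np.array(["endodormancy"] * n + ["ecodormancy"] * n)
    return X, y


class TestMultinomialFit:
    def test_separable_training_accuracy(self):
        X, y = _toy_two_class()
        clf = bp.fit_multinomial_lr(X, y, reg_grid=[1e-4, 1e-2])
        assert (clf.predict(pd.DataFrame(X)) == y).mean() == 1.0

    def test_probabilities_sum_to_one(self):
        X, y = _toy_two_class()
        clf = bp.fit_multinomial_lr(X, y)
        proba = clf.predict_proba(pd.DataFrame([[0.3, -1.2], [5, 5]]))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_symmetric_point_fifty_fifty(self):
        X, y = _toy_two_class(gap=4.0, seed=1)
        # symmetrize exactly: mirror the two clouds
        X = np.vstack([X, -X])
        y = np.concatenate([y, np.where(y == y[0], "ecodormancy",
                                        "endodormancy")])
        clf = bp.fit_multinomial_lr(X, y)
        proba = clf.predict_proba(pd.DataFrame([[0.0, 0.0]]))
        np.testing.assert_allclose(proba[0], [0.5, 0.5], atol=0.01)

    def test_label_permutation_chance_level(self):
        rng = np.random.default_rng(2)
        X, y = _toy_two_class(n=30, seed=2)
        y_perm = rng.permutation(y)
        clf = bp.fit_multinomial_lr(X, y_perm)
        acc = max(clf.cv_accuracy_.values())
        assert acc == pytest.approx(0.5, abs=0.15)

    def test_single_class_rejected(self):
        X = np.random.default_rng(3).normal(size=(10, 2))
        with pytest.raises(BudphaseError):
            bp.fit_multinomial_lr(X, ["endodormancy"] * 10)

    def test_gradient_norm_small_and_beats_random(self):
        X, y = _toy_two_class(seed=4)
        clf = bp.fit_multinomial_lr(X, y)
        classes = list(clf.classes_)
        y_idx = np.asarray([classes.index(v) for v in y])
        g = softmax_gradient_norm(clf.coef_, clf.intercept_, X, y_idx,
                                  clf.lambda_)
        assert g < 1e-6
        f_opt = penalized_nll(clf.coef_, clf.intercept_, X, y_idx,
                              clf.lambda_)
        rng = np.random.default_rng(5)
        for _ in range(100):
            coef = rng.normal(size=clf.coef_.shape)
            intercept = rng.normal(size=clf.intercept_.shape)
            assert f_opt <= penalized_nll(coef, intercept, X, y_idx,
                                          clf.lambda_) + 1e-9

    def test_cv_tie_prefers_stronger_regularization(self):
        X, y = _toy_two_class(gap=8.0, seed=6)
        clf = bp.fit_multinomial_lr(X, y, reg_grid=[1e-3, 1e-1])
        best = max(clf.cv_accuracy_.values())
        tied = [l for l, a in clf.cv_accuracy_.items() if a == best]
        if len(tied) > 1:
            assert clf.lambda_ == max(tied)

    def test_matches_sklearn_predictions(self):
        """Independent cross-check: sklearn's lbfgs multinomial fit at the
        same penalty predicts the same labels."""
        from sklearn.linear_model import LogisticRegression
        X, y = _toy_two_class(gap=2.0, seed=7)
        lam = 1.0
        coef, intercept, _ = _fit_softmax(
            X, np.asarray([0] * 30 + [1] * 30), 2, lam)
        sk = LogisticRegression(C=1.0 / lam, tol=1e-10, max_iter=5000)
        sk.fit(X, y)
        ours = np.argmax(X @ coef.T + intercept, axis=1)
        theirs = (sk.predict(X) == sk.classes_[1]).astype(int)
        agreement = max((ours == theirs).mean(), (ours != theirs).mean())
        assert agreement == 1.0

    def test_tie_broken_by_stage_order(self):
        clf = bp.StageClassifier(precomputed_scores=True)
        clf.classes_ = np.asarray(["endodormancy", "ecodormancy"])
        clf.pca_ = None
        clf.coef_ = np.zeros((2, 2))
        clf.intercept_ = np.zeros(2)
        pred = clf.predict(pd.DataFrame([[1.0, 1.0]]))
        assert pred[0] == "endodormancy"


class TestWeightedF1:
    def test_perfect(self):
        assert bp.weighted_f1(list("AAB"), list("AAB")) == pytest.approx(1.0)

    def test_hand_case(self):
        assert bp.weighted_f1(list("AAB"), list("ABB")) == pytest.approx(2 / 3)

    def test_total_miss(self):
        assert bp.weighted_f1(list("AB"), list("BA")) == pytest.approx(0.0)

    def test_matches_sklearn(self):
        from sklearn.metrics import f1_score
        rng = np.random.default_rng(0)
        y_true = rng.choice(list("ABC"), 60)
        y_pred = rng.choice(list("ABC"), 60)
        assert bp.weighted_f1(y_true, y_pred) == pytest.approx(
            f1_score(y_true, y_pred, average="weighted"))

    def test_equals_accuracy_balanced_no_class_swap(self):
        y_true = np.array(list("AABB"))
        y_pred = np.array(list("AABA"))
        # balanced support, predictions hit each class symmetrically
        f1 = bp.weighted_f1(y_true, y_pred)
        acc = (y_true == y_pred).mean()
        assert f1 <= acc  # F1 is bounded by accuracy here

    def test_empty_rejected(self):
        with pytest.raises(BudphaseError):
            bp.weighted_f1([], [])


class TestEvaluateSplits:
    def test_determinism(self):
        X, y = _toy_two_class(seed=8)
        r1 = bp.evaluate_splits(X, y, n_splits=5, seed=3,
                                reg_grid=[1e-2, 1.0])
        r2 = bp.evaluate_splits(X, y, n_splits=5, seed=3,
                                reg_grid=[1e-2, 1.0])
        np.testing.assert_array_equal(r1.f1_scores, r2.f1_scores)
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_clean_separation_perfect_f1(self):
        X, y = _toy_two_class(gap=10.0, seed=9)
        report = bp.evaluate_splits(X, y, n_splits=5, seed=0,
                                    reg_grid=[1e-3, 1e-1])
        assert report.mean_f1 == pytest.approx(1.0)

    def test_shuffled_labels_chance(self):
        rng = np.random.default_rng(10)
        X, y = _toy_two_class(n=40, seed=10)
        report = bp.evaluate_splits(X, rng.permutation(y), n_splits=10,
                                    seed=0, reg_grid=[1e-2, 1.0])
        assert report.mean_f1 < 0.75


class TestSerialization:
    def test_model_roundtrip(self, tmp_path):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=[f"m{i}" for i in range(5)])
        y = np.asarray((["organogenesis"] * 10 + ["endodormancy"] * 10
                        + ["dormancy_release"] * 10 + ["ecodormancy"] * 10))
        clf = bp.StageClassifier(reg_grid=[1e-2, 1.0]).fit(X, y)
        path = tmp_path / "model.json"
        clf.to_json(path)
        back = bp.StageClassifier.from_json(path)
        np.testing.assert_allclose(back.predict_proba(X),
                                   clf.predict_proba(X), atol=1e-12)
        assert list(back.classes_) == list(clf.classes_)


class TestChronology:
    def test_nondecreasing_sequence_scores_one(self):
        meta = bp.validate_metadata(pd.DataFrame({
            "sample_id": ["a", "b", "c"], "cultivar": "cv", "tree": "t",
            "date": ["2015-09-01", "2015-11-01", "2016-02-01"]}))
        preds = pd.Series(["paradormancy", "endodormancy", "ecodormancy"],
                          index=["a", "b", "c"])
        assert bp.stage_chronology_consistency(meta, preds) == 1.0

    def test_one_regression_flagged(self):
        meta = bp.validate_metadata(pd.DataFrame({
            "sample_id": ["a", "b", "c"], "cultivar": "cv", "tree": "t",
            "date": ["2015-09-01", "2015-11-01", "2016-02-01"]}))
        preds = pd.Series(["endodormancy", "paradormancy", "ecodormancy"],
                          index=["a", "b", "c"])
        assert bp.stage_chronology_consistency(meta, preds) == \
            pytest.approx(0.5)
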