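"""Linear SVM training, cross-validation metrics, pathologic ratio, follow-up."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

import gaitsubpop as g


def primal_objective(w, b, x, y, c=1.0):
    margins = 1.0 - y * (x @ w + b)
    return 0.5 * w @ w + c * np.clip(margins, 0, None).sum()


def dual_qp_solution(x, y, c=1.0):
    """Independent oracle: solve the SVM dual QP with SLSQP."""
    n = len(y)
    q = (y[:, None] * x) @ (y[:, None] * x).T

    def neg_dual(a):
        return 0.5 * a @ q @ a - a.sum()

    def neg_dual_grad(a):
        return q @ a - 1.0

    cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}
    res = minimize(
        neg_dual,
        np.full(n, c / 2),
        jac=neg_dual_grad,
        bounds=[(0, c)] * n,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    w = ((a * y)[:, None] * x).sum(axis=0)
    on_margin = (a > 1e-6 * c) & (a < c * (1 - 1e-6))
    if on_margin.any():
        b = np.mean(y[on_margin] - x[on_margin] @ w)
    else:
        b = 0.0
    return w, b


class TestTrain:
    def test_symmetric_separable_boundary_at_zero(self):
        path = np.array([[-1.0]] * 4)
        hc = np.array([[1.0]] * 4)
        w, b = g.train_linear_svm(path, hc)
        assert abs(b) < 1e-6
        assert float(np.array([1.0]) @ w + b) > 0  # HC side positive
        assert float(np.array([-1.0]) @ w + b) < 0

    def test_duplicating_points_leaves_model_unchanged(self, rng):
        # exact for separable data (no active hinge loss; duplication rescales
        # only the empirical loss term, which is zero at the optimum)
        path = rng.normal(-4, 1, size=(8, 3))
        hc = rng.normal(4, 1, size=(8, 3))
        w1, b1 = g.train_linear_svm(path, hc)
        w2, b2 = g.train_linear_svm(np.vstack([path, path]), np.vstack([hc, hc]))
        np.testing.assert_allclose(w1, w2, atol=1e-5)
        assert b1 == pytest.approx(b2, abs=1e-5)

    def test_matches_dual_qp_oracle(self, rng):
        x_path = rng.normal(-0.8, 1, size=(9, 2))
        x_hc = rng.normal(0.8, 1, size=(9, 2))
        w, b = g.train_linear_svm(x_path, x_hc)
        x = np.vstack([x_path, x_hc])
        y = np.concatenate([-np.ones(9), np.ones(9)])
        w_qp, b_qp = dual_qp_solution(x, y)
        obj = primal_objective(w, b, x, y)
        obj_qp = primal_objective(w_qp, b_qp, x, y)
        assert obj == pytest.approx(obj_qp, abs=1e-4)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="class"):
            g.train_linear_svm(rng.normal(size=(0, 2)), rng.normal(size=(5, 2)))

    def test_kernel_scale_contract(self, rng):
        # scaling features by c and kernel_scale by c leaves decisions unchanged
        path = rng.normal(-1, 1, size=(10, 3))
        hc = rng.normal(1, 1, size=(10, 3))
        probe = rng.normal(size=(5, 3))
        w1, b1 = g.train_linear_svm(path, hc, kernel_scale=1.0)
        c = 7.5
        w2, b2 = g.train_linear_svm(c * path, c * hc, kernel_scale=c)
        np.testing.assert_allclose(probe @ w1 + b1, (c * probe) @ w2 + b2, atol=1e-5)


class TestPathologicRatio:
    @pytest.mark.parametrize(
        "n_path,n_total,expected",
        [(23, 27, 85.2), (26, 42, 61.9), (18, 35, 51.4),
         (7, 16, 43.8), (14, 27, 51.9), (5, 18, 27.8), (0, 27, 0.0)],
    )
    def test_worked_examples(self, n_path, n_total, expected):
        assert g.pathologic_ratio(n_path, n_total) == expected

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            g.pathologic_ratio(1, 0)
        with pytest.raises(ValueError):
            g.pathologic_ratio(5, 3)

    @settings(max_examples=100, deadline=None)
    @given(n_total=st.integers(1, 500), data=st.data())
    def test_complement_identity(self, n_total, data):
        n = data.draw(st.integers(0, n_total))
        unrounded = 100.0 * n / n_total + 100.0 * (n_total - n) / n_total
        assert unrounded == pytest.approx(100.0, abs=1e-9)


class TestCrossValidation:
    def test_perfect_separation(self, rng):
        path = rng.normal(size=(15, 2)) + np.array([-20, 0])
        hc = rng.normal(size=(15, 2)) + np.array([20, 0])
        clf = g.crossvalidate_10fold(path, hc, seed=0)
        assert clf.report.classification_rate == 100.0
        assert clf.report.roc_auc == 1.0
        assert clf.report.pathologic_ratio == 100.0
        assert clf.report.sensitivity == 1.0 and clf.report.specificity == 1.0

    def test_out_of_fold_predictions_cover_everyone_once(self, rng):
        path = rng.normal(size=(14, 3))
        hc = rng.normal(size=(16, 3))
        clf = g.crossvalidate_10fold(path, hc, seed=1)
        assert len(clf.cv_predictions) == 30
        assert clf.cv_predictions.subject_id.is_unique

    def test_shuffled_labels_give_chance_auc(self):
        # permutation simulation: mean AUC over 100 random-label datasets ~ 0.5
        aucs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.normal(size=(200, 2))
            split = r.permutation(200)
            clf = g.crossvalidate_10fold(x[split[:100]], x[split[100:]], seed=seed)
            aucs.append(clf.report.roc_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_fold_reduction_warns(self, rng, caplog):
        path = rng.normal(-3, 1, size=(5, 2))
        hc = rng.normal(3, 1, size=(20, 2))
        with caplog.at_level(logging.WARNING, logger="gaitsubpop.svm"):
            g.crossvalidate_10fold(path, hc, seed=0)
        assert any("reducing folds" in r.message for r in caplog.records)

    def test_auc_invariant_to_monotone_transform(self, rng):
        path = rng.normal(-0.5, 1, size=(20, 2))
        hc = rng.normal(0.5, 1, size=(20, 2))
        clf = g.crossvalidate_10fold(path, hc, seed=3)
        d = clf.cv_predictions.decision_value.to_numpy()
        y = (clf.cv_predictions.true_class == "pathologic").astype(int)
        a1 = roc_auc_score(y, -d)
        a2 = roc_auc_score(y, -(np.exp(d) + 5 * d))  # strictly increasing transform
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert a1 == pytest.approx(clf.report.roc_auc, abs=1e-12)


class TestFollowup:
    def test_counts_and_ratio(self, rng):
        path = rng.normal(-2, 1, size=(20, 2))
        hc = rng.normal(2, 1, size=(25, 2))
        clf = g.crossvalidate_10fold(path, hc, seed=0)
        fu = rng.normal(0.5, 1.5, size=(16, 2))
        rep = g.project_followup(clf, fu, hc)
        assert rep.n_classified_pathologic + rep.n_classified_hc == 16
        assert rep.pathologic_ratio == g.pathologic_ratio(rep.n_classified_pathologic, 16)
        assert rep.sensitivity == pytest.approx(rep.pathologic_ratio / 100, abs=0.05)
        assert rep.era == "post"

    def test_hc_mean_point_classified_by_orientation(self, rng):
        path = rng.normal(-2, 1, size=(20, 2))
        hc = rng.normal(2, 1, size=(25, 2))
        clf = g.crossvalidate_10fold(path, hc, seed=0)
        hc_mean = hc.mean(axis=0, keepdims=True)
        rep = g.project_followup(clf, hc_mean, hc)
        if clf.decision(hc_mean)[0] > 0:
            assert rep.n_classified_pathologic == 0

    def test_dimension_mismatch_rejected(self, rng):
        path = rng.normal(-2, 1, size=(10, 2))
        hc = rng.normal(2, 1, size=(10, 2))
        clf = g.crossvalidate_10fold(path, hc, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            g.project_followup(clf, rng.normal(size=(3, 5)), hc)
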