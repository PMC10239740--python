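"""PCA, NIPALS PLS1, OPLS-DA, DQ² and leave-one-out cross-validation."""
import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import seminalomics as so
from seminalomics.chemometrics import NipalsPLS, OPLSDA

from conftest import two_class_data


def pm1(y):
    return np.where(np.asarray(y) == np.unique(y)[1], 1.0, -1.0)


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.arange(1.0, 9.0)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        res = so.pca(u @ v, 1)
        assert res.explained_variance_pct[0] == pytest.approx(100.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(0)
        res = so.pca(rng.standard_normal((30, 8)), 5)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-10)

    def test_variance_percentages(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 6))
        full = so.pca(X, 6)
        assert np.all(np.diff(full.explained_variance_pct) <= 1e-12)
        assert full.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-8)
        part = so.pca(X, 3)
        assert part.explained_variance_pct.sum() < 100.0

    def test_rank_k_reconstruction_matches_svd_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 10))
        k = 4
        res = so.pca(X, k)
        recon = res.scores @ res.loadings.T + X.mean(axis=0)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc)
        best = (U[:, :k] * s[:k]) @ Vt[:k] + X.mean(axis=0)
        assert np.allclose(recon, best, atol=1e-10)

    def test_k_beyond_rank_rejected(self):
        X = np.outer(np.arange(6.0), np.ones(4))
        with pytest.raises(ValueError, match="rank"):
            so.pca(X, 3)


class TestPls:
    def test_single_variable_slope_equals_ols(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(25)
        y = 2.0 * x + rng.standard_normal(25) * 0.3
        model = so.pls_fit(x[:, None], y, 1)
        xc = x - x.mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        assert model.coef_[0] == pytest.approx(slope, rel=1e-10)

    def test_full_rank_fit_equals_least_squares(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        model = so.pls_fit(X, y, 5)
        Xc = np.column_stack([np.ones(20), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        assert np.allclose(model.predict(X), Xc @ beta, atol=1e-8)

    def test_matches_sklearn_pls_coefficients(self):
        """Independent engine: sklearn's NIPALS-based PLSRegression."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 12))
        y = rng.standard_normal(30)
        ours = so.pls_fit(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(ours.coef_, ref.coef_.ravel(), atol=1e-8)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(6)
        model = so.pls_fit(rng.standard_normal((25, 10)), rng.standard_normal(25), 4)
        G = model.x_scores_.T @ model.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        perm = rng.permutation(20)
        a = so.pls_fit(X, y, 2)
        b = so.pls_fit(X[perm], y[perm], 2)
        assert np.allclose(a.x_scores_[perm], b.x_scores_, atol=1e-10)
        assert np.allclose(a.coef_, b.coef_, atol=1e-10)

    def test_components_beyond_rank_rejected(self):
        X = np.outer(np.arange(10.0), np.ones(3))
        with pytest.raises(ValueError):
            so.pls_fit(X, np.arange(10.0), 2)


class TestOplsDa:
    def test_zero_orthogonal_equals_pls1(self):
        X, y = two_class_data(seed=8)
        o = so.opls_da_fit(X, y, 0)
        p = NipalsPLS(n_components=1).fit(X, pm1(y))
        assert np.allclose(o.decision_function(X), p.predict(X), atol=1e-10)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_opls_pls_prediction_equivalence(self, k):
        """OPLS with 1+k components predicts like PLS with k+1."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            X = rng.standard_normal((20, 50))
            y = np.where(rng.random(20) > 0.5, "a", "b")
            if len(np.unique(y)) < 2:
                continue
            o = so.opls_da_fit(X, y, k)
            p = NipalsPLS(n_components=k + 1).fit(X, pm1(y))
            assert np.max(np.abs(o.decision_function(X) - p.predict(X))) < 1e-8

    def test_orthogonal_scores_uncorrelated_with_y(self):
        X, y = two_class_data(n_per_class=15, seed=10)
        o = so.opls_da_fit(X, y, 2)
        yv = pm1(y)
        for a in range(o.n_orth_):
            t = o.t_orth_[:, a]
            assert abs(np.corrcoef(t, yv)[0, 1]) < 1e-8

    def test_r2y_nondecreasing_in_n_orth(self):
        X, y = two_class_data(n_per_class=12, n_features=20, seed=11)
        r2 = [so.opls_da_fit(X, y, k).r2y_ for k in range(4)]
        assert np.all(np.diff(r2) >= -1e-12)
        assert 0.0 <= r2[0] <= 1.0

    def test_negative_n_orth_rejected(self):
        X, y = two_class_data()
        with pytest.raises(ValueError):
            so.opls_da_fit(X, y, -1)

    def test_predict_returns_original_labels(self):
        X, y = two_class_data(d=4.0, seed=12)
        model = so.opls_da_fit(X, y, 1)
        assert set(model.predict(X)) <= {"low", "high"}
        assert (model.predict(X) == y).mean() > 0.95


class TestDq2:
    def test_perfect_prediction(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        assert so.dq2(y, y) == pytest.approx(1.0)

    def test_beyond_label_predictions_not_penalized(self):
        y = np.array([1.0, -1.0])
        yhat = np.array([1.7, -1.3])
        assert so.dq2(y, yhat) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        yhat = np.full(4, y.mean())
        assert so.dq2(y, yhat) == pytest.approx(0.0)

    def test_all_equal_labels_rejected(self):
        with pytest.raises(ValueError):
            so.dq2(np.ones(4), np.ones(4))

    def test_matches_bruteforce_oracle_and_dominates_q2(self):
        """1000 random label/prediction pairs against an independently
        coded clipped-residual formula; clipping can only raise Q2."""
        rng = np.random.default_rng(13)
        for _ in range(1000):
            n = rng.integers(4, 12)
            y = rng.choice([-1.0, 1.0], n)
            if len(np.unique(y)) < 2:
                continue
            yhat = rng.normal(0, 1.5, n)
            press = 0.0
            for yi, fi in zip(y, yhat):
                r = yi - fi
                if yi == 1.0 and fi > 1.0:
                    r = 0.0
                if yi == -1.0 and fi < -1.0:
                    r = 0.0
                press += r * r
            tss = float(np.sum((y - y.mean()) ** 2))
            expected = 1.0 - press / tss
            got = so.dq2(y, yhat)
            assert got == pytest.approx(expected, abs=1e-12)
            q2 = 1.0 - float(np.sum((y - yhat) ** 2)) / tss
            assert got >= q2 - 1e-12


class TestLooCv:
    def test_separated_classes_classified_perfectly(self):
        X, y = two_class_data(n_per_class=20, n_informative=5, d=5.0, seed=14)
        res = so.loo_cv(X, y, 0)
        assert res.accuracy_cv == 100.0
        assert len(res.yhat) == 40
        assert res.dq2y > 0.8

    def test_single_member_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError):
            so.loo_cv(X, y, 0)

    def test_permutation_null_dq2_near_zero(self):
        """Label permutations give mean LOO DQ2 <= 0.05 (chance level)."""
        rng = np.random.default_rng(15)
        X = rng.standard_normal((24, 15))
        y = np.array(["a", "b"] * 12)
        vals = []
        for _ in range(30):
            vals.append(so.loo_cv(X, rng.permutation(y), 0).dq2y)
        assert np.mean(vals) <= 0.05


class TestSelectOrthogonal:
    def test_no_orthogonal_structure_selects_zero(self):
        X, y = two_class_data(n_per_class=20, n_informative=8, d=2.0, seed=16)
        assert so.select_n_orthogonal(X, y, 3) == 0

    def test_bounded_and_deterministic(self):
        X, y = two_class_data(n_per_class=10, seed=17)
        k1 = so.select_n_orthogonal(X, y, 2)
        k2 = so.select_n_orthogonal(X, y, 2)
        assert k1 == k2 <= 2

    def test_structured_orthogonal_variation_detected(self):
        """A strong y-uncorrelated latent factor should be stripped."""
        rng = np.random.default_rng(18)
        n, p = 40, 30
        y = np.array(["a"] * 20 + ["b"] * 20)
        X = rng.standard_normal((n, p)) * 0.5
        X[y == "b", :5] += 1.2
        confound = rng.standard_normal(n)
        X += np.outer(confound, rng.standard_normal(p)) * 2.0
        assert so.select_n_orthogonal(X, y, 2) >= 1
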