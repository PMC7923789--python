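"""PCA and NIPALS PLS1 against closed-form and library oracles."""
import numpy as np
import pandas as pd
import pytest

from wormspectra import lv1_loading_spectrum, pca_fit, pls1_fit, preprocess
from wormspectra.multivariate import AUTOSCALE, MEAN_CENTER


@pytest.fixture
def random_matrix(rng):
    return rng.normal(size=(12, 5)) * np.array([1.0, 3.0, 0.5, 10.0, 2.0])


class TestPreprocess:
    def test_mean_centering(self, random_matrix):
        Xp, _ = preprocess(random_matrix, MEAN_CENTER)
        assert np.allclose(Xp.mean(axis=0), 0.0, atol=1e-12)

    def test_autoscaling(self, random_matrix):
        Xp, _ = preprocess(random_matrix, AUTOSCALE)
        assert np.allclose(Xp.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Xp.std(axis=0, ddof=1), 1.0)

    def test_constant_column_flagged_and_left_centered(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        Xp, pre = preprocess(X, AUTOSCALE)
        assert pre.constant_columns.tolist() == [False, True]
        assert np.allclose(Xp[:, 1], 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.ones((1, 3)))


class TestPCA:
    def test_perfectly_collinear_data_is_one_component(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, 2.0 * x])
        model = pca_fit(X, 1, MEAN_CENTER)
        assert model.explained_variance_pct[0] == pytest.approx(100.0)

    def test_full_rank_explains_everything(self, random_matrix):
        model = pca_fit(random_matrix, 5, MEAN_CENTER)
        assert model.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(model.explained_variance_pct) <= 1e-9)

    def test_loadings_orthonormal(self, random_matrix):
        model = pca_fit(random_matrix, 4, AUTOSCALE)
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(4), atol=1e-10)

    def test_component_variances_match_eigen_oracle(self, rng):
        X = rng.normal(size=(4, 3))
        model = pca_fit(X, 3, MEAN_CENTER)
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        assert np.allclose(model.singular_values**2, eigvals[: 3], atol=1e-9)

    def test_full_reconstruction(self, random_matrix):
        model = pca_fit(random_matrix, 5, AUTOSCALE)
        Xp, _ = preprocess(random_matrix, AUTOSCALE)
        assert np.allclose(model.reconstruct(), Xp, atol=1e-9)

    def test_too_many_components_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            pca_fit(random_matrix, 6)


class TestPLS1:
    def test_exact_linear_response_is_fully_calibrated(self, rng):
        # orthogonal predictors: one LV then isolates the generating column
        raw = rng.normal(size=(20, 6))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered + orthonormal
        y = 3.0 * X[:, 2] + 1.0
        model = pls1_fit(X, y, n_lv=1)
        assert model.r2_calibration == pytest.approx(1.0, abs=1e-9)

    def test_single_predictor_equals_ols_slope(self, rng):
        x = rng.normal(size=30)
        y = 2.0 + 0.7 * x + rng.normal(0, 0.3, 30)
        model = pls1_fit(x[:, None], y, n_lv=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coef_[0] == pytest.approx(slope, abs=1e-9)

    def test_full_rank_pls_matches_ols_predictions(self, rng):
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        model = pls1_fit(X, y, n_lv=4)
        A = np.column_stack([np.ones(25), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(model.predict(X), A @ beta, atol=1e-6)

    def test_r2_non_decreasing_in_components(self, rng):
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 1.0, 30)
        r2 = [pls1_fit(X, y, n_lv=k).r2_calibration for k in range(1, 7)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_random_response_calibrates_worse_than_exact(self, rng):
        X = rng.normal(size=(50, 5))
        noise_model = pls1_fit(X, rng.normal(size=50), n_lv=1)
        exact_model = pls1_fit(X, X[:, 0], n_lv=1)
        assert noise_model.r2_calibration < exact_model.r2_calibration

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError):
            pls1_fit(rng.normal(size=(10, 3)), np.ones(10))

    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.5, 30)
        ours = pls1_fit(X, y, n_lv=3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(ours.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_score_response_covariance_positive(self, rng):
        X = rng.normal(size=(40, 6))
        y = -2.0 * X[:, 1] + rng.normal(0, 0.2, 40)  # anti-correlated construction
        model = pls1_fit(X, y, n_lv=2)
        yc = y - y.mean()
        for k in range(model.n_lv):
            assert model.x_scores[:, k] @ yc >= 0


class TestLV1LoadingSpectrum:
    def test_records_in_bin_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 100)), columns=[f"bin_{i:02d}" for i in range(100)])
        y = X.to_numpy() @ rng.normal(size=100)
        out = lv1_loading_spectrum(pls1_fit(X, y, n_lv=1))
        assert len(out) == 100
        assert out["variable"].tolist() == [f"bin_{i:02d}" for i in range(100)]

    def test_loadings_positive_where_response_is_built(self, rng):
        # y grows with occupancy of bins 70-89; LV1 must load positively there
        n = 60
        raw = rng.dirichlet(np.ones(100), size=n) * 100.0
        y = raw[:, 70:90].sum(axis=1) + rng.normal(0, 0.05, n)
        model = pls1_fit(raw, y, n_lv=1)
        lv1 = model.x_loadings[:, 0]
        assert lv1[70:90].mean() > 0
        assert lv1[70:90].mean() > lv1[:70].mean()
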