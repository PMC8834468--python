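"""PLS-1 engine: oracles, cross-validation, dimensionality rules."""

import numpy as np
import pytest

from scmwpls.pls import (
    batched_pls1_ssr,
    loo_rmsecv,
    max_lv_for_region,
    load_model,
    pls1_fit,
    pls1_predict,
    rmsec_curve,
    save_model,
    ssr,
)


def sklearn_pls_predictions(X, y, k):
    """Independent oracle: scikit-learn's SVD/NIPALS PLS regression."""
    from sklearn.cross_decomposition import PLSRegression

    m = PLSRegression(n_components=k, scale=False).fit(X, y.reshape(-1, 1))
    return m.predict(X).ravel()


class TestFit:
    def test_single_proportional_column_is_exact(self, rng):
        y = rng.normal(size=12)
        X = (2.0 * y)[:, None]
        model = pls1_fit(X, y, 1)
        assert np.allclose(pls1_predict(model, X), y, atol=1e-10)
        assert model.rmsec < 1e-10

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        model = pls1_fit(X, y, 8)
        Xc = X - X.mean(0)
        b = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        ols = Xc @ b + y.mean()
        assert np.allclose(pls1_predict(model, X), ols, atol=1e-8)

    @pytest.mark.parametrize("n,h", [(8, 4), (12, 10), (20, 8)])
    def test_matches_independent_oracle_at_every_k(self, rng, n, h):
        X = rng.normal(size=(n, h))
        y = rng.normal(size=n)
        for k in range(1, min(n - 1, h) + 1):
            ours = pls1_predict(pls1_fit(X, y, k), X)
            assert np.allclose(ours, sklearn_pls_predictions(X, y, k), atol=1e-8)

    def test_scores_orthogonal(self, rng):
        from scmwpls.pls import _nipals
        from scmwpls.preprocess import mean_center

        X = rng.normal(size=(15, 9))
        y = rng.normal(size=15)
        Xc, yc, _, _ = mean_center(X, y)
        W, P, q, _ = _nipals(Xc, yc, 5)
        # reconstruct score vectors factor by factor
        Xd = Xc.copy()
        T = []
        for j in range(5):
            t = Xd @ W[:, j]
            Xd -= np.outer(t, P[:, j])
            T.append(t)
        T = np.column_stack(T)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError, match="infeasible"):
            pls1_fit(rng.normal(size=(5, 3)), rng.normal(size=5), 5)

    def test_zero_variance_y_errors(self, rng):
        with pytest.raises(ValueError, match="variance"):
            pls1_fit(rng.normal(size=(5, 3)), np.ones(5), 1)

    def test_deterministic(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m1, m2 = pls1_fit(X, y, 3), pls1_fit(X, y, 3)
        assert np.array_equal(m1.coefficients, m2.coefficients)

    def test_global_column_scaling_invariance(self, rng):
        X = rng.normal(size=(15, 7))
        y = rng.normal(size=15)
        for k in (1, 3, 5):
            p1 = pls1_predict(pls1_fit(X, y, k), X)
            p2 = pls1_predict(pls1_fit(7.3 * X, y, k), 7.3 * X)
            assert np.allclose(p1, p2, atol=1e-8)


class TestPredict:
    def test_training_predictions_recovered(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = pls1_fit(X, y, 2)
        fitted = pls1_predict(model, X)
        assert model.rmsec == pytest.approx(
            np.sqrt(np.mean((fitted - y) ** 2)), abs=1e-12
        )

    def test_mean_row_predicts_mean_response(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = pls1_fit(X, y, 2)
        assert pls1_predict(model, X.mean(0))[0] == pytest.approx(model.y_mean)

    def test_hand_computed_example(self):
        # two samples, two channels: y = first channel exactly
        X = np.array([[1.0, 0.0], [3.0, 0.0]])
        y = np.array([1.0, 3.0])
        model = pls1_fit(X, y, 1)
        # centered X column 1 is (-1, 1); b must be (1, 0)
        assert np.allclose(model.coefficients, [1.0, 0.0], atol=1e-12)
        assert np.allclose(pls1_predict(model, np.array([[2.0, 5.0]])), [2.0])

    def test_column_mismatch_errors(self, rng):
        model = pls1_fit(rng.normal(size=(8, 4)), rng.normal(size=8), 2)
        with pytest.raises(ValueError, match="channels"):
            pls1_predict(model, rng.normal(size=(3, 5)))


class TestSSR:
    def test_perfect_problem_is_zero(self, rng):
        y = rng.normal(size=10)
        assert ssr((3.0 * y)[:, None], y, 1) < 1e-18

    def test_equals_n_times_rmsec_squared(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        for k in (1, 3):
            model = pls1_fit(X, y, k)
            assert ssr(X, y, k) == pytest.approx(15 * model.rmsec**2, rel=1e-10)

    def test_matches_oracle_residuals(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        for k in (1, 2, 4):
            oracle = np.sum((sklearn_pls_predictions(X, y, k) - y) ** 2)
            assert ssr(X, y, k) == pytest.approx(oracle, abs=1e-10)


class TestLooCV:
    def test_one_latent_direction_chooses_one(self, rng):
        t = rng.normal(size=30)
        loadings = rng.normal(size=6)
        X = np.outer(t, loadings) + rng.normal(scale=1e-3, size=(30, 6))
        y = 2.0 * t + rng.normal(scale=1e-2, size=30)
        cv = loo_rmsecv(X, y, 4)
        assert cv.chosen_lv == 1
        assert np.argmin(cv.rmsecv_by_lv) == 0

    def test_strictly_decreasing_curve_warns_and_takes_kmax(self, rng):
        # full-rank noise-free linear relation: every LV helps
        X = rng.normal(size=(20, 4))
        b = rng.normal(size=4)
        y = X @ b
        with pytest.warns(UserWarning, match="decreasing"):
            cv = loo_rmsecv(X, y, 3)
        assert cv.chosen_lv == 3

    def test_each_fold_matches_manual_refit(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        k = 2
        press = 0.0
        for i in range(9):
            mask = np.ones(9, dtype=bool)
            mask[i] = False
            model = pls1_fit(X[mask], y[mask], k)
            press += (pls1_predict(model, X[i : i + 1])[0] - y[i]) ** 2
        cv = loo_rmsecv(X, y, 3)
        assert cv.rmsecv_by_lv[k - 1] == pytest.approx(np.sqrt(press / 9), abs=1e-10)

    def test_infeasible_kmax_errors(self, rng):
        with pytest.raises(ValueError, match="infeasible"):
            loo_rmsecv(rng.normal(size=(5, 8)), rng.normal(size=5), 4)


class TestMaxLv:
    def test_exact_one_factor_gives_one(self, rng):
        y = rng.normal(size=20)
        X = np.outer(y, rng.normal(size=8))
        X += rng.normal(scale=1e-8, size=X.shape)
        assert max_lv_for_region(X, y, k_cap=10) == 1

    def test_cap_of_one(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        assert max_lv_for_region(X, y, k_cap=1) == 1

    def test_three_factor_data_detected(self, rng):
        # three latent directions of distinct strength; enough samples that
        # a fourth factor can only chew an insignificant share of the noise
        n = 300
        T = rng.normal(size=(n, 3)) * np.array([5.0, 3.0, 2.0])
        L = rng.normal(size=(3, 10))
        X = T @ L + rng.normal(scale=1e-3, size=(n, 10))
        y = T @ np.array([1.0, 1.0, 1.0]) + rng.normal(scale=0.5, size=n)
        assert max_lv_for_region(X, y, k_cap=10) == 3


class TestInvariants:
    def test_rmsec_non_increasing_in_k(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 16))
            h = int(rng.integers(3, 10))
            X = rng.normal(size=(n, h))
            y = rng.normal(size=n)
            k = min(n - 1, h)
            curve = rmsec_curve(X, y, k)
            assert np.all(np.diff(curve) <= 1e-12)

    def test_batched_engine_matches_direct_fits(self, rng):
        X = rng.normal(size=(12, 30))
        y = rng.normal(size=12)
        H = 9
        V = np.lib.stride_tricks.sliding_window_view(X, H, axis=1)
        V = np.ascontiguousarray(V.transpose(1, 0, 2))
        S = batched_pls1_ssr(V, y, 4)
        for i in range(0, V.shape[0], 5):
            for k in (1, 2, 4):
                assert S[i, k - 1] == pytest.approx(
                    ssr(X[:, i : i + H], y, k), abs=1e-9
                )


class TestSerialization:
    def test_roundtrip(self, rng, tmp_path):
        from scmwpls.grid import RegionSet
        from scmwpls.preprocess import PreprocessSpec

        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = pls1_fit(
            X, y, 2,
            region_set=RegionSet.from_string("6000-5968"),
            preprocess=PreprocessSpec(),
            analyte="ethanol",
        )
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.allclose(back.coefficients, model.coefficients)
        assert back.n_lv == model.n_lv
        assert str(back.region_set) == str(model.region_set)
        assert np.allclose(pls1_predict(back, X), pls1_predict(model, X))
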