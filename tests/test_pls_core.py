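"""NIPALS PLS tests: orthogonality invariants, the pseudo-inverse oracle at
full rank, an explicit leave-one-out loop oracle, the component-selection
rule, and ground-truth recovery on bilinear synthetic data."""

import numpy as np
import pytest

import voltachemo as vc
from voltachemo.errors import ConfigurationError, DomainError
from voltachemo.pls_core import CVResult


def make_cv_result(curve):
    """CVResult carrying a given pooled RMSECV curve (single response)."""
    curve = np.asarray(curve, dtype=float)[:, None]
    n = 10
    return CVResult(curve, n * curve ** 2,
                    np.zeros((curve.shape[0], n, 1)), "synthetic", n)


class TestPLSFit:
    def test_rank_one_system_fits_exactly_with_one_component(self, rng):
        # X and Y share a single latent direction; one component suffices
        t = rng.normal(size=8)
        X = np.outer(t, rng.normal(size=5))
        Y = np.outer(t, [1.0, -2.0])
        model = vc.pls_fit(X, Y, 1)
        np.testing.assert_allclose(vc.pls_predict(model, X), Y,
                                   atol=1e-8 * np.abs(Y).max())

    def test_full_rank_model_equals_least_squares_oracle(self, rng):
        X = rng.normal(size=(8, 5))
        Y = rng.normal(size=(8, 2))
        model = vc.pls_fit(X, Y, 5)
        # oracle: ordinary least squares on the centred data via pinv
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        B_ols = np.linalg.pinv(Xc) @ Yc
        np.testing.assert_allclose(model.B, B_ols, rtol=1e-6, atol=1e-10)
        X_new = rng.normal(size=(4, 5))
        ols_pred = (X_new - X.mean(0)) @ B_ols + Y.mean(0)
        np.testing.assert_allclose(vc.pls_predict(model, X_new), ols_pred,
                                   rtol=1e-6)

    def test_score_orthogonality_and_unit_weights(self, rng):
        X = rng.normal(size=(20, 30))
        Y = rng.normal(size=(20, 3))
        model = vc.pls_fit(X, Y, 5)
        gram = model.T.T @ model.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.linalg.norm(gram)
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0,
                                   rtol=1e-10)

    def test_agrees_with_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(12, 9))
        Y = rng.normal(size=(12, 2))
        model = vc.pls_fit(X, Y, 3)
        sk = sklearn.PLSRegression(n_components=3, scale=False,
                                   tol=1e-12, max_iter=2000).fit(X, Y)
        np.testing.assert_allclose(vc.pls_predict(model, X), sk.predict(X),
                                   rtol=1e-4, atol=1e-6)

    def test_zero_variance_response_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        Y = np.column_stack([np.ones(6), rng.normal(size=6)])
        with pytest.raises(DomainError):
            vc.pls_fit(X, Y, 2)

    def test_component_count_bounds_enforced(self, rng):
        X = rng.normal(size=(6, 4))
        Y = rng.normal(size=(6, 1))
        with pytest.raises(ConfigurationError):
            vc.pls_fit(X, Y, 6)


class TestPLSPredict:
    def test_training_predictions_equal_fitted_values(self, rng):
        X = rng.normal(size=(10, 7))
        Y = rng.normal(size=(10, 2))
        model = vc.pls_fit(X, Y, 3)
        np.testing.assert_array_equal(vc.pls_predict(model, X),
                                      vc.pls_predict(model, X.copy()))

    def test_duplicated_rows_give_duplicated_predictions(self, rng):
        X = rng.normal(size=(10, 7))
        Y = rng.normal(size=(10, 2))
        model = vc.pls_fit(X, Y, 3)
        pred = vc.pls_predict(model, np.stack([X[0], X[0]]))
        np.testing.assert_array_equal(pred[0], pred[1])

    def test_noiseless_ternary_mixtures_recovered_with_three_components(
            self, design_table, clean_simulation):
        vset, _ = clean_simulation
        model = vc.pls_fit(vset.matrix[:16], design_table.values[:16], 3,
                           x_mode="pareto")
        pred = vc.pls_predict(model, vset.matrix[16:])
        np.testing.assert_allclose(pred, design_table.values[16:],
                                   rtol=1e-3)

    def test_predictions_invariant_to_response_units(self, rng):
        # with autoscaled responses, rescaling a Y column is a pure change
        # of units and must not move the predictions
        X = rng.normal(size=(12, 8))
        Y = rng.normal(size=(12, 2))
        m1 = vc.pls_fit(X, Y, 3, y_mode="autoscale")
        Y2 = Y.copy()
        Y2[:, 1] *= 1000.0
        m2 = vc.pls_fit(X, Y2, 3, y_mode="autoscale")
        p1 = vc.pls_predict(m1, X)
        p2 = vc.pls_predict(m2, X)
        np.testing.assert_allclose(p2[:, 1] / 1000.0, p1[:, 1], rtol=1e-10)
        np.testing.assert_allclose(p2[:, 0], p1[:, 0], rtol=1e-10)

    def test_column_mismatch_rejected(self, rng):
        model = vc.pls_fit(rng.normal(size=(6, 4)),
                           rng.normal(size=(6, 1)), 2)
        with pytest.raises(DomainError):
            vc.pls_predict(model, rng.normal(size=(3, 5)))


class TestCrossValidate:
    def test_matches_explicit_leave_one_out_loop(self, rng):
        X = rng.normal(size=(6, 4))
        Y = rng.normal(size=(6, 2))
        cv = vc.cross_validate(X, Y, 2, "loo")
        # oracle: refit and predict each held-out row by hand
        for a in (1, 2):
            press = np.zeros(2)
            for i in range(6):
                keep = [j for j in range(6) if j != i]
                m = vc.pls_fit(X[keep], Y[keep], a)
                press += (vc.pls_predict(m, X[i]) - Y[i]) ** 2
            np.testing.assert_allclose(cv.press[a - 1], press, rtol=1e-8)

    def test_press_equals_n_times_squared_rmsecv(self, rng):
        X = rng.normal(size=(8, 5))
        Y = rng.normal(size=(8, 1))
        cv = vc.cross_validate(X, Y, 3, "loo")
        np.testing.assert_allclose(cv.press, cv.n * cv.rmsecv ** 2,
                                   rtol=1e-12)

    def test_rmsecv_curves_finite_and_nonnegative(self, rng):
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 2))
        cv = vc.cross_validate(X, Y, 4, ("kfold", 5), seed=1)
        assert np.all(np.isfinite(cv.rmsecv)) and np.all(cv.rmsecv >= 0)

    def test_error_drops_to_the_true_rank_on_synthetic_mixtures(
            self, design_table, max_apex):
        art = vc.ArtifactSpec("none", 0.0, 0.0, 1e-3 * max_apex, seed=4)
        vset = vc.generate_mixture_set(design_table, artifacts=art)
        cv = vc.cross_validate(vset.matrix[:16], design_table.values[:16],
                               4, "loo", x_mode="pareto")
        pooled = np.sqrt((cv.rmsecv ** 2).mean(axis=1))
        assert pooled[0] > pooled[1] > pooled[2]

    def test_excessive_component_request_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            vc.cross_validate(rng.normal(size=(5, 4)),
                              rng.normal(size=(5, 1)), 4, "loo")


class TestSelectNLv:
    def test_flat_curve_selects_one_component(self):
        assert vc.select_n_lv(make_cv_result([1.0, 1.0, 1.0, 1.0])) == 1

    def test_two_percent_rule_on_a_knee_curve(self):
        assert vc.select_n_lv(
            make_cv_result([10.0, 4.0, 1.0, 0.99, 0.985])) == 3

    def test_noiseless_rank_three_data_selects_three(self, design_table,
                                                     clean_simulation):
        vset, _ = clean_simulation
        cv = vc.cross_validate(vset.matrix[:16], design_table.values[:16],
                               5, "loo", x_mode="pareto")
        assert vc.select_n_lv(cv) == 3


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 2))
        model = vc.pls_fit(X, Y, 3, x_mode="pareto")
        path = tmp_path / "model.json"
        vc.model_to_json(model, path)
        back = vc.model_from_json(path)
        np.testing.assert_array_equal(vc.pls_predict(back, X),
                                      vc.pls_predict(model, X))
        assert back.n_lv == model.n_lv
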