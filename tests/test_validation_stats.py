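"""Validation-statistics tests: RMSE/REP identities, the printed ANOVA
table reproduction, permutation behaviour, and dense-matrix oracles for
leverage and Hotelling T2."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

import voltachemo as vc
from voltachemo.errors import DegenerateSystemError, DomainError
from voltachemo.validation_stats import CvAnovaRow, r_squared


class TestErrorStats:
    def test_perfect_predictions(self):
        es = vc.error_stats(np.array([1.0, 2.0, 3.0]),
                            np.array([1.0, 2.0, 3.0]))
        assert es.rmse == 0.0 and es.rep_percent == 0.0
        assert es.r2 == pytest.approx(1.0)

    def test_hand_computed_case(self):
        es = vc.error_stats(np.array([1.0, 2.0, 3.0]),
                            np.array([1.0, 2.0, 5.0]))
        assert es.rmse == pytest.approx(math.sqrt(4.0 / 3.0), rel=1e-12)
        assert es.y_mean == pytest.approx(8.0 / 3.0, rel=1e-12)
        assert es.rep_percent == pytest.approx(43.30, abs=0.01)

    def test_rep_identity_for_random_vectors(self, rng):
        for _ in range(10):
            pred = rng.normal(loc=5.0, size=12)
            act = rng.normal(loc=5.0, size=12)
            es = vc.error_stats(pred, act)
            assert es.rep_percent == pytest.approx(
                100.0 * es.rmse / es.y_mean, rel=1e-12)

    def test_published_after_filter_row_is_internally_consistent(self):
        # RMSEP 1.98e-6 at REP 0.48% implies a mean nominal level of
        # 4.125e-4 mol/L, which must lie inside levodopa's linear range
        y_mean = 100.0 * 1.98e-6 / 0.48
        assert y_mean == pytest.approx(4.125e-4, rel=1e-12)
        lo, hi = vc.LEVODOPA.linear_range
        assert lo < y_mean < hi

    def test_zero_mean_marks_rep_undefined(self):
        es = vc.error_stats(np.array([1.0, -1.0]), np.array([1.0, -1.0]))
        assert math.isnan(es.rep_percent)


class TestCvAnova:
    # printed decomposition: (ss_total, ss_residual, df_total, df_reg,
    #                         expected F, expected p)
    PRINTED = [
        ("LD", 24.0, 13.46, 24, 20, 0.157, 0.998),
        ("CD", 24.0, 4.19, 24, 20, 0.947, 0.596),
        ("ENT", 24.0, 7.71, 24, 20, 0.423, 0.912),
    ]

    @pytest.mark.parametrize("name,sst,ssr,dft,dfr,f_exp,p_exp", PRINTED)
    def test_reproduces_printed_f_statistics(self, name, sst, ssr, dft,
                                             dfr, f_exp, p_exp):
        row = CvAnovaRow.from_sums(sst, ssr, dft, dfr)
        assert row.f == pytest.approx(f_exp, abs=0.005)
        assert row.p == pytest.approx(p_exp, abs=0.005)

    def test_reproduces_printed_sd_columns(self):
        row = CvAnovaRow.from_sums(24.0, 13.46, 24, 20)
        assert row.sd_regression == pytest.approx(0.726, abs=0.005)
        assert row.sd_residual == pytest.approx(1.83, abs=0.01)

    def test_p_value_matches_numeric_integration_of_f_density(self):
        row = CvAnovaRow.from_sums(24.0, 13.46, 24, 20)
        tail, _ = integrate.quad(lambda x: stats.f.pdf(x, 20, 4),
                                 row.f, np.inf)
        assert row.p == pytest.approx(tail, abs=1e-6)

    def test_additivity_invariants_hold_by_construction(self, rng):
        y = rng.normal(size=25)
        y = (y - y.mean()) / y.std(ddof=1)
        resid = rng.normal(scale=0.4, size=25)
        row = vc.cv_anova(y, resid)
        assert row.ss_total == pytest.approx(
            row.ss_regression + row.ss_residual, rel=1e-12)
        assert row.df_total == row.df_regression + row.df_residual
        assert row.df_total == 24 and row.df_regression == 20
        assert row.f == pytest.approx(row.ms_regression / row.ms_residual,
                                      rel=1e-12)

    def test_zero_residual_yields_infinite_f(self):
        row = CvAnovaRow.from_sums(24.0, 0.0, 24, 20)
        assert math.isinf(row.f) and row.p == 0.0


class TestPermutationTest:
    def _signal_data(self, seed=0):
        design = vc.map_levels_to_concentrations(
            vc.brereton_design(5, 3),
            {a.name: a.linear_range for a in vc.DEFAULT_ANALYTES})
        vset = vc.generate_mixture_set(design,
                                       artifacts=vc.ArtifactSpec.none(seed))
        return vset.matrix[:16], design.values[:16, 0]

    def test_original_point_enters_at_unit_correlation(self):
        X, y = self._signal_data()
        res = vc.permutation_test(X, y, 3, n_perm=10, seed=1,
                                  x_mode="pareto")
        assert res.correlations[0] == 1.0
        assert np.all(res.r2_values <= 1.0 + 1e-12)

    def test_identity_permutation_reproduces_original_r2(self):
        X, y = self._signal_data()
        model = vc.pls_fit(X, y, 3, x_mode="pareto")
        assert r_squared(model, X, y) == pytest.approx(1.0, abs=1e-6)

    def test_valid_model_beats_every_permutation(self):
        X, y = self._signal_data()
        res = vc.permutation_test(X, y, 3, n_perm=15, seed=2,
                                  x_mode="pareto")
        assert res.q2_original > res.q2_values[1:].max()
        assert res.r2_original > res.r2_values[1:].max()
        assert res.q2_intercept < 0.0

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(DomainError):
            vc.permutation_test(rng.normal(size=(8, 5)),
                                rng.normal(size=8), 2, n_perm=5)


class TestLeverages:
    def test_diagonal_matches_dense_projection_oracle(self, rng):
        X = rng.normal(size=(12, 9))
        Y = rng.normal(size=(12, 2))
        model = vc.pls_fit(X, Y, 2)
        hx, hy = vc.leverages(model)
        for scores, h in ((model.T, hx), (model.U, hy)):
            dense = scores @ np.linalg.inv(scores.T @ scores) @ scores.T
            np.testing.assert_allclose(h, np.diag(dense), rtol=1e-10)

    def test_trace_equals_component_count_and_bounds(self, rng):
        X = rng.normal(size=(15, 10))
        Y = rng.normal(size=(15, 3))
        for a in (1, 2, 4):
            model = vc.pls_fit(X, Y, a)
            hx, hy = vc.leverages(model)
            assert hx.sum() == pytest.approx(a, rel=1e-10)
            assert hy.sum() == pytest.approx(a, rel=1e-10)
            assert np.all(hx > -1e-12) and np.all(hx < 1 + 1e-12)


class TestHotellingT2:
    def test_mean_t2_identity_for_centred_scores(self, rng):
        X = rng.normal(size=(20, 8))
        Y = rng.normal(size=(20, 2))
        model = vc.pls_fit(X, Y, 2)
        t2, _ = vc.hotelling_t2(model)
        n, a = model.T.shape
        assert t2.mean() == pytest.approx(a * (n - 1) / n, rel=1e-10)
        assert np.all(t2 >= 0)

    def test_critical_value_matches_independent_quantile(self):
        # independent route: invert the F CDF numerically instead of
        # calling the quantile function
        alpha, a, n = 0.05, 2, 20
        f_quantile = optimize.brentq(
            lambda x: stats.f.cdf(x, a, n - a) - (1 - alpha), 1e-9, 1e3)
        expected = a * (n - 1) * (n + 1) / (n * (n - a)) * f_quantile
        rng = np.random.default_rng(3)
        model = vc.pls_fit(rng.normal(size=(n, 6)),
                           rng.normal(size=(n, 1)), a)
        _, crit = vc.hotelling_t2(model, alpha=alpha)
        assert crit == pytest.approx(expected, rel=1e-9)

    def test_sample_at_model_centre_scores_zero(self, rng):
        X = rng.normal(size=(9, 5))
        X = np.vstack([X, X.mean(axis=0)])    # last sample = column means
        Y = rng.normal(size=(10, 1))
        model = vc.pls_fit(X, Y, 2)
        t2, _ = vc.hotelling_t2(model)
        assert t2[-1] == pytest.approx(0.0, abs=1e-16)

    def test_too_many_components_rejected(self, rng):
        # as many score columns as samples leaves no residual df
        model = vc.pls_fit(rng.normal(size=(6, 8)),
                           rng.normal(size=(6, 1)), 3)
        square = vc.PLSModel(3, model.W, model.T[:3], model.P,
                             model.U[:3], model.Q, model.B,
                             model.x_scaling, model.y_scaling)
        with pytest.raises(DomainError):
            vc.hotelling_t2(square)


class TestStandardizedResiduals:
    def test_alternating_unit_residuals_standardise_to_one(self):
        z, flags = vc.standardized_residuals(
            np.array([1.0, -1.0, 1.0, -1.0]), np.zeros(4))
        np.testing.assert_allclose(np.abs(z), 1.0, rtol=1e-12)
        assert not flags.any()

    def test_perfect_fit_has_no_flags(self):
        z, flags = vc.standardized_residuals(np.ones(5), np.ones(5))
        assert not z.any() and not flags.any()

    def test_single_gross_outlier_flagged_alone(self, rng):
        act = np.zeros(21)
        pred = rng.normal(scale=0.1, size=21)
        pred[7] = 5.0
        _, flags = vc.standardized_residuals(pred, act)
        assert flags[7] and flags.sum() == 1

    def test_normal_probability_coords_are_sorted_pairs(self, rng):
        z, _ = vc.standardized_residuals(rng.normal(size=15),
                                         np.zeros(15))
        q, zs = vc.normal_probability_coords(z)
        assert np.all(np.diff(q) > 0)
        np.testing.assert_array_equal(zs, np.sort(z))
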