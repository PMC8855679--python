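import numpy as np
import pytest
from scipy import stats

import assayrsm as ar
from assayrsm.datasets import FULL_TERMS, REFERENCE_COEFFICIENTS, SELECTED_TERMS
from assayrsm.rsm import SingularDesignError, UndefinedAICcError
from conftest import ols_normal_equations

# Published estimates of the selected model and their 95% CI bounds,
# in SELECTED_TERMS order (intercept, linear x3, phenol:acid,
# acid:water, three-way, acid^2, water^2).
PUBLISHED_BETA = [
    0.2869, 0.003508, 0.04769, -0.08491, 0.021, 0.047, -0.018, -0.05295, -0.02061,
]
PUBLISHED_CI = [
    (0.2736, 0.3002),
    (-0.006887, 0.01390),
    (0.03730, 0.05809),
    (-0.09531, -0.07452),
    (0.007418, 0.03458),
    (0.03342, 0.06058),
    (-0.03158, -0.004418),
    (-0.06302, -0.04289),
    (-0.03068, -0.01054),
]


class TestDesignMatrix:
    def test_center_row_is_intercept_only(self):
        row = ar.build_design_matrix(np.zeros((1, 3)), SELECTED_TERMS)[0]
        expected = np.zeros(9)
        expected[0] = 1.0
        assert np.array_equal(row, expected)

    def test_three_way_product_sign(self):
        terms = ar.ModelTerms(((0, 0, 0), (1, 1, 1)))
        row = ar.build_design_matrix(np.array([[1.0, 1.0, -1.0]]), terms)[0]
        assert row[1] == -1.0

    def test_axial_square_entry(self):
        terms = ar.ModelTerms(((0, 0, 0), (0, 2, 0)))
        row = ar.build_design_matrix(np.array([[0.0, -1.682, 0.0]]), terms)[0]
        assert row[1] == pytest.approx(2.829, abs=5e-4)


class TestFitOLS:
    def test_reproduces_published_estimates_to_4_sig_figs(self, selected_fit):
        for got, want in zip(selected_fit.beta, PUBLISHED_BETA):
            assert got == pytest.approx(want, rel=5e-4)
        assert selected_fit.r2 == pytest.approx(0.9834, abs=5e-5)
        assert selected_fit.r2_adj == pytest.approx(0.9713, abs=5e-5)

    def test_reproduces_published_ci_bounds(self, selected_fit):
        for (lo, hi), (plo, phi) in zip(selected_fit.ci95(), PUBLISHED_CI):
            assert lo == pytest.approx(plo, abs=5e-4)
            assert hi == pytest.approx(phi, abs=5e-4)

    def test_agrees_with_normal_equations_oracle(self, experiment, selected_fit):
        X = ar.build_design_matrix(experiment.design, SELECTED_TERMS)
        beta, cov, rss = ols_normal_equations(X, experiment.y)
        assert np.allclose(selected_fit.beta, beta, atol=1e-12)
        assert np.allclose(selected_fit.cov, cov, atol=1e-12)
        assert selected_fit.rss == pytest.approx(rss, abs=1e-14)

    def test_zero_noise_recovers_exactly(self, experiment):
        X = ar.build_design_matrix(experiment.design, SELECTED_TERMS)
        truth = np.array(list(REFERENCE_COEFFICIENTS.values()))
        fit = ar.fit_ols(X, X @ truth, SELECTED_TERMS)
        assert np.allclose(fit.beta, truth, atol=1e-12)

    def test_constant_response_gives_intercept_only(self, experiment):
        X = ar.build_design_matrix(experiment.design, SELECTED_TERMS)
        fit = ar.fit_ols(X, np.full(20, 0.42), SELECTED_TERMS)
        assert fit.beta[0] == pytest.approx(0.42, abs=1e-12)
        assert np.allclose(fit.beta[1:], 0.0, atol=1e-12)

    def test_rank_deficient_design_raises(self):
        X = np.ones((10, 2))  # duplicated intercept column
        with pytest.raises(SingularDesignError):
            ar.fit_ols(X, np.arange(10.0), ar.ModelTerms(((0,), (1,))))

    def test_residuals_orthogonal_to_columns(self, experiment, selected_fit):
        X = ar.build_design_matrix(experiment.design, SELECTED_TERMS)
        resid = experiment.y - X @ selected_fit.beta
        assert np.allclose(X.T @ resid, 0.0, atol=1e-10)

    def test_r2_adj_below_r2(self, selected_fit, full_fit):
        assert selected_fit.r2_adj <= selected_fit.r2
        assert full_fit.r2_adj <= full_fit.r2


class TestReduceModel:
    def test_drops_phenol_square_and_phenol_water(self, full_fit):
        kept = ar.reduce_model(full_fit, alpha=0.05)
        removed = set(FULL_TERMS) - set(kept)
        assert removed == {(2, 0, 0), (1, 0, 1)}
        # linear phenol survives by hierarchy despite p ~ 0.49
        assert (1, 0, 0) in kept.terms
        assert set(kept) == set(SELECTED_TERMS)

    def test_no_removal_when_all_terms_strong(self, experiment):
        X = ar.build_design_matrix(experiment.design, FULL_TERMS)
        rng = np.random.default_rng(0)
        strong = rng.uniform(0.5, 1.0, size=len(FULL_TERMS))
        y = np.abs(X @ strong) + rng.normal(0, 1e-4, 20)
        fit = ar.fit_ols(X, y, FULL_TERMS)
        assert set(ar.reduce_model(fit)) == set(FULL_TERMS)

    def test_null_square_term_removed_in_most_replicates(self, experiment):
        # the true surface has no phenol-square term; simulate, refit the
        # full model, and check the term is dropped in >= 90% of replicates
        removed = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = ar.SurfaceSimConfig(seed=seed)
            ms = ar.simulate_surface_measurements(cfg, experiment.design)
            fit = ar.fit_measurements(ms, FULL_TERMS)
            if (2, 0, 0) not in ar.reduce_model(fit).terms:
                removed += 1
        assert removed / n_rep >= 0.90

    def test_intercept_never_removed(self, experiment):
        X = ar.build_design_matrix(experiment.design, SELECTED_TERMS)
        rng = np.random.default_rng(1)
        fit = ar.fit_ols(X, np.abs(rng.normal(0, 1, 20)), SELECTED_TERMS)
        assert (0, 0, 0) in ar.reduce_model(fit).terms


class TestAICc:
    def test_identical_fits(self, selected_fit):
        delta, prob = ar.compare_aicc(selected_fit, selected_fit)
        assert delta == 0.0
        assert prob == 0.5

    def test_selected_vs_full(self, selected_fit, full_fit):
        delta, prob = ar.compare_aicc(selected_fit, full_fit)
        assert delta == pytest.approx(-20.93, abs=5e-3)
        assert prob > 0.9999

    def test_antisymmetry(self, selected_fit, full_fit):
        d_ab, p_ab = ar.compare_aicc(selected_fit, full_fit)
        d_ba, p_ba = ar.compare_aicc(full_fit, selected_fit)
        assert d_ab == pytest.approx(-d_ba)
        assert p_ab + p_ba == pytest.approx(1.0)

    def test_undefined_when_saturated(self):
        # n - K - 1 <= 0: 5 rows, 4 coefficients, K = 5
        terms = ar.ModelTerms(((0,), (1,), (2,), (3,)))
        x = np.linspace(-1, 1, 5)[:, None]
        X = ar.build_design_matrix(x, terms)
        fit = ar.fit_ols(X, np.array([1.0, 2.0, 2.5, 2.0, 1.0]), terms)
        assert np.isnan(fit.aicc)
        with pytest.raises(UndefinedAICcError):
            ar.aicc(fit)


class TestPredict:
    def test_origin_returns_intercept(self, selected_fit):
        est, (lo, hi) = ar.predict(selected_fit, [0.0, 0.0, 0.0])
        assert est == pytest.approx(0.2869, rel=5e-4)
        assert lo < est < hi

    def test_zero_noise_fit_predicts_truth(self, experiment):
        X = ar.build_design_matrix(experiment.design, SELECTED_TERMS)
        truth = np.array(list(REFERENCE_COEFFICIENTS.values()))
        fit = ar.fit_ols(X, X @ truth, SELECTED_TERMS)
        pt = [0.5, -0.3, 0.8]
        x_row = ar.build_design_matrix(np.array([pt]), SELECTED_TERMS)[0]
        est, _ = ar.predict(fit, pt)
        assert est == pytest.approx(float(x_row @ truth), abs=1e-10)

    def test_verification_condition_matches_covariance_oracle(
        self, experiment, selected_fit
    ):
        # the published verification condition 2: coded (0.7, 0, -1.682)
        pt = np.array([0.7, 0.0, -1.682])
        X = ar.build_design_matrix(experiment.design, SELECTED_TERMS)
        beta, cov, _ = ols_normal_equations(X, experiment.y)
        x = ar.build_design_matrix(pt[None, :], SELECTED_TERMS)[0]
        want = float(x @ beta)
        half = stats.t.ppf(0.975, 11) * np.sqrt(x @ cov @ x)
        est, (lo, hi) = ar.predict(selected_fit, pt)
        assert est == pytest.approx(want, abs=1e-12)
        assert lo == pytest.approx(want - half, abs=1e-10)
        assert hi == pytest.approx(want + half, abs=1e-10)

    def test_extrapolation_warns(self, selected_fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            ar.predict(selected_fit, [3.0, 0.0, 0.0])


class TestCenterPointDrift:
    def test_packaged_experiment_is_stable(self, experiment):
        d = ar.center_point_drift(experiment)
        assert d.mean == pytest.approx(0.291, abs=1e-3)
        assert d.mad == pytest.approx(0.008, abs=5e-4)
        assert d.passed
        assert list(d.order) == [1, 6, 7, 11, 17, 20]

    def test_identical_centers_pass_with_zero_mad(self, three_factors):
        table = ar.generate_ccd(three_factors, n_center=6, seed=0)
        y = np.where(table.center_mask(), 0.3, 0.2)
        d = ar.center_point_drift(ar.MeasurementSet(table, y))
        assert d.mad == 0.0
        assert d.passed

    def test_unstable_centers_fail(self, three_factors):
        table = ar.generate_ccd(three_factors, n_center=2, seed=0)
        y = np.full(len(table.runs), 0.5)
        y[0], y[-1] = 1.0, 1.2
        d = ar.center_point_drift(ar.MeasurementSet(table, y))
        assert d.mad == pytest.approx(0.1)
        assert d.mad_over_mean == pytest.approx(0.1 / 1.1)
        assert not d.passed

    def test_requires_two_center_points(self, experiment):
        runs = [r for r in experiment.design.runs if r.point_type != "center"][:10]
        design = ar.DesignTable(runs=runs, seed=-1, n_center=0)
        ms = ar.MeasurementSet(design, np.full(len(runs), 0.2))
        with pytest.raises(ValueError, match="center points"):
            ar.center_point_drift(ms)
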