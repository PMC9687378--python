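import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bayesabc as B
from bayesabc.gmm_bayes import chi_square_gof, em_fit, gmm_density


class TestTransforms:
    @pytest.mark.parametrize(
        "value,pseudocount,expected",
        [(1000.0, 0.0, 3.0), (0.0, 1.0, 0.0), (912.0, 0.0, 2.96)],
    )
    def test_log_transform_examples(self, value, pseudocount, expected):
        assert B.log_transform(value, pseudocount=pseudocount) == pytest.approx(
            expected, abs=5e-3
        )

    @pytest.mark.parametrize("x_log,expected", [(2.96, 912.0), (1.48, 30.2), (0.0, 1.0)])
    def test_back_transform_examples(self, x_log, expected):
        got = B.back_transform(x_log)
        # agreement to 3 significant figures
        assert float(f"{got:.3g}") == pytest.approx(expected)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_back_transform_inverts_log_transform(self, value):
        assert B.back_transform(B.log_transform(value)) == pytest.approx(
            value, rel=1e-9
        )

    def test_log_transform_monotone(self):
        x = np.sort(np.random.default_rng(0).uniform(0.1, 100, 50))
        assert np.all(np.diff(B.log_transform(x)) > 0)


class TestDensity:
    def test_single_standard_normal_peak(self):
        model = B.GaussianMixtureModel((B.GaussianComponent(1.0, 0.0, 1.0),))
        assert gmm_density(model, 0.0) == pytest.approx(1 / math.sqrt(2 * math.pi))

    def test_symmetric_pair_equals_component_average(self):
        pair = B.GaussianMixtureModel(
            (B.GaussianComponent(0.5, -2.0, 1.0), B.GaussianComponent(0.5, 2.0, 1.0))
        )
        single = B.GaussianMixtureModel((B.GaussianComponent(1.0, 2.0, 1.0),))
        # at the symmetry point both components contribute equally
        assert gmm_density(pair, 0.0) == pytest.approx(gmm_density(single, 0.0))

    def test_matches_term_by_term_sum(self, skew_model):
        x = 2.5
        expected = sum(
            c.w * math.exp(-0.5 * ((x - c.m) / c.s) ** 2) / (c.s * math.sqrt(2 * math.pi))
            for c in skew_model.components
        )
        assert gmm_density(skew_model, x) == pytest.approx(expected, rel=1e-12)

    def test_integrates_to_one(self, skew_model):
        grid = np.linspace(-10, 15, 20001)
        area = np.trapezoid(skew_model.pdf(grid), grid)
        assert area == pytest.approx(1.0, abs=1e-6)


class TestPosterior:
    def test_equal_components_split_evenly_at_midpoint(self):
        model = B.GaussianMixtureModel(
            (B.GaussianComponent(0.5, 0.0, 1.0), B.GaussianComponent(0.5, 4.0, 1.0))
        )
        assert B.posterior(model, 2.0, 0) == pytest.approx(0.5)
        assert B.posterior(model, 2.0, 1) == pytest.approx(0.5)

    def test_high_component_dominates_at_its_mean(self, skew_model):
        assert B.posterior(skew_model, 4.0, 1) > 0.5

    def test_matches_direct_bayes_formula(self, skew_model):
        x = 2.5
        num = [
            c.w * math.exp(-0.5 * ((x - c.m) / c.s) ** 2) / (c.s * math.sqrt(2 * math.pi))
            for c in skew_model.components
        ]
        for i in (0, 1):
            assert B.posterior(skew_model, x, i) == pytest.approx(
                num[i] / sum(num), rel=1e-12
            )

    def test_posteriors_sum_to_one_even_in_extreme_tails(self, skew_model):
        x = np.array([-60.0, -10.0, 0.0, 2.5, 10.0, 60.0])
        r = skew_model.responsibilities(x)
        assert np.all(np.isfinite(r))
        assert np.allclose(r.sum(axis=1), 1.0, atol=1e-9)


class TestEMFitting:
    def test_loglik_trace_is_monotone(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(1, 0.5, 2000), rng.normal(4, 0.5, 2000)])
        _, _, _, trace = em_fit(
            x, np.array([0.5, 0.5]), np.array([0.0, 5.0]), np.array([1.0, 1.0]),
            s_floor=1e-6,
        )
        assert len(trace) > 3
        assert np.all(np.diff(trace) >= -1e-10)

    def test_single_gaussian_selected_and_recovered(self):
        x = np.random.default_rng(11).normal(2.0, 1.0, 20000)
        model = B.fit_gmm(x, seed=0)
        assert model.M == 1
        assert abs(model.means[0] - 2.0) < 0.05
        assert abs(model.sds[0] - 1.0) < 0.05

    def test_mixture_parameters_recovered(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(1, 0.5, 30000), rng.normal(4, 0.5, 20000)])
        model = B.fit_gmm(x, m_candidates=[2], seed=0)
        assert np.allclose(model.weights, [0.6, 0.4], atol=0.05)
        assert np.allclose(model.means, [1.0, 4.0], atol=0.05)
        assert np.allclose(model.sds, [0.5, 0.5], atol=0.05)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(1, 0.4, 8000), rng.normal(3.5, 0.6, 4000)])
        ours = B.fit_gmm(x, m_candidates=[2], seed=0)
        ref = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8).fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        assert np.allclose(ours.means, ref.means_.ravel()[order], atol=0.02)
        assert np.allclose(ours.weights, ref.weights_[order], atol=0.02)
        assert np.allclose(
            ours.sds, np.sqrt(ref.covariances_.ravel()[order]), atol=0.02
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            B.fit_gmm(np.arange(10.0))


class TestDecisionBorder:
    def test_symmetric_model_has_midpoint_border(self):
        model = B.GaussianMixtureModel(
            (B.GaussianComponent(0.5, 0.0, 1.0), B.GaussianComponent(0.5, 4.0, 1.0))
        )
        border = B.decision_border(model)
        assert border.x_log == pytest.approx(2.0, abs=1e-9)
        assert border.x_raw == pytest.approx(100.0, rel=1e-8)

    @pytest.mark.parametrize(
        "w,s", [(0.5, 0.4), (0.7, 0.5), (0.3, 0.3), (0.9, 0.6)]
    )
    def test_posterior_at_border_is_half(self, w, s):
        model = B.GaussianMixtureModel(
            (B.GaussianComponent(w, 1.0, s), B.GaussianComponent(1 - w, 4.0, s))
        )
        border = B.decision_border(model)
        assert abs(B.posterior_high(model, border.x_log) - 0.5) < 1e-8

    def test_matches_brute_force_grid_scan(self):
        model = B.GaussianMixtureModel(
            (B.GaussianComponent(0.7, 1.0, 0.5), B.GaussianComponent(0.3, 4.0, 0.5))
        )
        border = B.decision_border(model)
        grid = np.arange(1.0, 4.0, 1e-6)
        scan = grid[np.argmin(np.abs(B.posterior_high(model, grid) - 0.5))]
        assert abs(border.x_log - scan) < 1e-5

    def test_fitted_model_border_on_synthetic_data(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(1.8, 0.35, 10000), rng.normal(3.4, 0.35, 10000)])
        model = B.fit_gmm(x, m_candidates=[2], seed=0)
        border = B.decision_border(model)
        assert abs(B.posterior_high(model, border.x_log) - 0.5) < 1e-8
        assert 1.8 < border.x_log < 3.4


class TestNormalize:
    def test_elementwise_matches_scalar_posterior(self, skew_model):
        rng = np.random.default_rng(1)
        logm = rng.uniform(-1, 6, size=(50, 10))
        out = B.normalize_to_posteriors(skew_model, logm)
        assert out.shape == logm.shape
        for i, j in [(0, 0), (10, 3), (49, 9)]:
            assert out[i, j] == pytest.approx(
                B.posterior(skew_model, logm[i, j], 1), rel=1e-12
            )

    def test_border_maps_to_half_and_limits_saturate(self, sharp_model):
        border = B.decision_border(sharp_model)
        vals = np.array([[border.x_log, -30.0, 30.0]])
        out = B.normalize_to_posteriors(sharp_model, vals)
        assert out[0, 0] == pytest.approx(0.5, abs=1e-8)
        assert out[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert out[0, 2] == pytest.approx(1.0, abs=1e-12)
        assert np.all((out >= 0) & (out <= 1))


class TestGoodnessOfFit:
    def test_perfectly_matching_bins_give_zero_statistic(self, sharp_model):
        reps = 100
        centers = [(i + 0.5) / 50 for i in range(50)]
        x = np.repeat([sharp_model.quantile(c) for c in centers], reps)
        res = chi_square_gof(sharp_model, x)
        assert res.chi2_stat < 1e-6
        assert res.p_value == pytest.approx(1.0)
        assert res.observed.sum() == x.size

    def test_calibration_under_the_true_model(self, sharp_model):
        # data generated from the fitted model family: p-values should be
        # roughly uniform; at alpha=0.01 the rejection rate stays small
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(30):
            comp = rng.random(3000) < 0.5
            x = np.where(comp, rng.normal(1, 0.3, 3000), rng.normal(4, 0.3, 3000))
            model = B.fit_gmm(x, m_candidates=[2], seed=1, n_restarts=3)
            pvals.append(chi_square_gof(model, x).p_value)
        pvals = np.array(pvals)
        assert (pvals < 0.01).mean() <= 0.1
        assert 0.15 < np.median(pvals) < 0.95

    def test_rejects_heavy_tailed_data(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = np.concatenate(
                [1 + 0.4 * rng.standard_t(2, 4000), 4 + 0.4 * rng.standard_t(2, 4000)]
            )
            model = B.fit_gmm(x, m_candidates=[2], seed=1, n_restarts=3)
            assert chi_square_gof(model, x).p_value < 0.01

    def test_expected_counts_respect_minimum(self, sharp_model):
        x = np.random.default_rng(9).normal(2.5, 1.2, 150)
        res = chi_square_gof(sharp_model, x, min_expected=5)
        assert np.all(res.expected >= 5)
        assert res.observed.size >= 3
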