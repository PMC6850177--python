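"""Deterministic demographic machinery: links, matrices, projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aphidpop as ap
from aphidpop.demography import PlantSizeSeries


def make_coeffs(survival=None, growth=None, reproduction=None,
                density_scale=None) -> ap.CoefficientSet:
    betas = np.zeros((3, 14))
    for row, vals in enumerate((survival, growth, reproduction)):
        if vals is not None:
            betas[row, :len(vals)] = vals
    return ap.CoefficientSet(betas=betas, density_scale=density_scale)


class TestLinearPredictor:
    @pytest.mark.parametrize("survival, cov, expected", [
        (None, ap.Covariates(123.0, "B", 1), 0.0),
        ([1.0, -0.001, 0.5], ap.Covariates(1000.0, "A", 0), 0.5),
        ([1.0, -0.001, 0.5, 0, 0, 0, 0, 0, -0.2],
         ap.Covariates(1000.0, "A", 1), 0.3),
    ])
    def test_indicator_selected_terms(self, survival, cov, expected):
        c = make_coeffs(survival=survival)
        assert ap.linear_predictor(c, "survival", cov) == pytest.approx(expected)

    def test_accepts_one_based_treatment_index(self):
        c = make_coeffs(survival=[0, 0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        for i, label in enumerate(("A", "B", "C", "AB", "AC", "BC"), start=1):
            by_label = ap.linear_predictor(c, "survival",
                                           ap.Covariates(0.0, label, 0))
            by_index = ap.linear_predictor(c, "survival",
                                           ap.Covariates(0.0, i, 0))
            assert by_label == by_index == pytest.approx(0.1 * i)

    def test_unknown_treatment_raises(self):
        c = make_coeffs()
        with pytest.raises(ValueError, match="treatment"):
            ap.linear_predictor(c, "survival", ap.Covariates(0.0, "Z", 0))
        with pytest.raises(ValueError):
            ap.linear_predictor(c, "survival", ap.Covariates(0.0, 7, 0))

    def test_density_standardization_and_raw_equivalence(self):
        c = make_coeffs(growth=[0.5, 0.2], density_scale=(800.0, 700.0))
        cov = ap.Covariates(1500.0, "A", 0)
        scaled = ap.linear_predictor(c, "growth", cov)
        assert scaled == pytest.approx(0.5 + 0.2 * (1500 - 800) / 700)
        raw = c.to_raw()
        assert ap.linear_predictor(raw, "growth", cov) == pytest.approx(scaled)


class TestVitalRatesAt:
    def test_zero_coefficients_hit_link_midpoints(self):
        v = ap.vital_rates_at(make_coeffs(), ap.Covariates(5.0, "C", 0))
        assert v.sigma == pytest.approx(0.5)
        assert v.gamma == pytest.approx(0.5)
        assert v.phi == pytest.approx(1.0)

    def test_links_saturate_not_overflow(self):
        c = make_coeffs(survival=[1e4], growth=[-1e4], reproduction=[1e4])
        v = ap.vital_rates_at(c, ap.Covariates(0.0, "A", 0))
        assert v.sigma == pytest.approx(1.0)
        assert v.gamma == pytest.approx(0.0)
        assert np.isfinite(v.phi)

    def test_log_link_for_reproduction(self):
        c = make_coeffs(reproduction=[np.log(2.0)])
        v = ap.vital_rates_at(c, ap.Covariates(0.0, "A", 0))
        assert v.phi == pytest.approx(2.0)


class TestTransitionMatrix:
    @pytest.mark.parametrize("rates, expected", [
        ((0.9, 0.5, 1.0), [[0.45, 0, 1.0], [0.45, 0.45, 0], [0, 0.45, 0.9]]),
        ((1.0, 1.0, 0.0), [[0, 0, 0], [1, 0, 0], [0, 1, 1]]),
        ((0.95, 0.39, 0.89),
         [[0.5795, 0, 0.89], [0.3705, 0.5795, 0], [0, 0.3705, 0.95]]),
    ])
    def test_structure(self, rates, expected):
        A = ap.build_transition_matrix(ap.VitalRates(*rates))
        np.testing.assert_allclose(A, expected, atol=1e-12)

    @given(sigma=st.floats(0.01, 0.999), gamma=st.floats(0.0, 0.999),
           phi=st.floats(0.0, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_column_sum_identity(self, sigma, gamma, phi):
        A = ap.build_transition_matrix(ap.VitalRates(sigma, gamma, phi))
        assert A[:, 0].sum() == pytest.approx(sigma, abs=1e-12)
        assert A[:, 1].sum() == pytest.approx(sigma, abs=1e-12)
        assert A[:, 2].sum() == pytest.approx(sigma + phi, abs=1e-12)
        assert A[0, 1] == A[1, 2] == A[2, 0] == 0.0

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ap.VitalRates(0.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            ap.VitalRates(0.9, 1.5, 1.0)
        with pytest.raises(ValueError):
            ap.VitalRates(0.9, 0.5, -0.1)


class TestGrowthRate:
    def test_triangular_case_equals_sigma(self):
        A = ap.build_transition_matrix(ap.VitalRates(0.9, 0.5, 0.0))
        assert ap.asymptotic_growth_rate(A) == pytest.approx(0.9)

    def test_stasis(self):
        A = ap.build_transition_matrix(ap.VitalRates(1.0, 0.0, 0.0))
        assert ap.asymptotic_growth_rate(A) == pytest.approx(1.0)

    def test_reproducing_population(self):
        # root of (0.45-l)^2 (0.9-l) + 0.2025 = 0, located by bisection
        A = ap.build_transition_matrix(ap.VitalRates(0.9, 0.5, 1.0))
        assert ap.asymptotic_growth_rate(A) == pytest.approx(1.2315, abs=5e-5)

    def test_agrees_with_power_iteration(self, rng):
        for _ in range(100):
            v = ap.VitalRates(rng.uniform(0.05, 0.99), rng.uniform(0, 0.99),
                              rng.uniform(0, 5))
            A = ap.build_transition_matrix(v)
            x = np.ones(3)
            for _ in range(4000):
                x = A @ x
                x /= np.linalg.norm(x)
            lam = float(x @ (A @ x))
            assert ap.asymptotic_growth_rate(A) == pytest.approx(lam, abs=1e-8)


class TestMeanFirstPassage:
    @pytest.mark.parametrize("gamma, expected",
                             [(0.5, 5.0), (1.0, 3.0), (0.2, 11.0)])
    def test_formula(self, gamma, expected):
        assert ap.mean_first_passage_time(gamma) == pytest.approx(expected)

    @pytest.mark.parametrize("gamma", [0.0, -0.3, 1.2])
    def test_invalid_gamma(self, gamma):
        with pytest.raises(ValueError):
            ap.mean_first_passage_time(gamma)


class TestProjection:
    def flat_plant(self, leaves=10.0, days=40):
        return PlantSizeSeries(start_day=0, values=np.full(days, leaves))

    def test_deterministic_advance(self):
        c = make_coeffs(survival=[1e4], growth=[1e4], reproduction=[-1e4])
        out = ap.project_interval([0, 20, 0], c, "A", lambda d: 0,
                                  self.flat_plant(), t0=0, dt=1)
        np.testing.assert_allclose(out, [0, 0, 20], atol=1e-6)
        out2 = ap.project_interval([0, 20, 0], c, "A", lambda d: 0,
                                   self.flat_plant(), t0=0, dt=2)
        np.testing.assert_allclose(out2, [0, 0, 20], atol=1e-6)

    def test_single_step_equals_matrix_product(self, truth):
        plant = self.flat_plant(leaves=7.0)
        n0 = np.array([3.0, 5.0, 12.0])
        cov = ap.Covariates(n0.sum() / 7.0, "B", 0)
        A = ap.build_transition_matrix(ap.vital_rates_at(truth, cov))
        out = ap.project_interval(n0, truth, "B", lambda d: 0, plant, 0, 1)
        np.testing.assert_allclose(out, A @ n0, rtol=1e-12)

    def test_density_dependent_interval_matches_hand_loop(self, truth):
        plant = PlantSizeSeries(0, np.array([8.0, 9.0, 11.0, 12.0]))
        n = np.array([4.0, 6.0, 10.0])
        expected = n.copy()
        for day in range(3):
            cov = ap.Covariates(expected.sum() / plant.leaves(day), "AC",
                                1 if day >= 2 else 0)
            A = ap.build_transition_matrix(ap.vital_rates_at(truth, cov))
            expected = A @ expected
        got = ap.project_interval(n, truth, "AC",
                                  lambda d: 1 if d >= 2 else 0, plant, 0, 3)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_no_density_effect_equals_matrix_power(self, rng):
        betas = np.zeros((3, 14))
        betas[:, 0] = [1.5, -0.2, 0.1]
        c = ap.CoefficientSet(betas=betas)
        plant = self.flat_plant(leaves=5.0)
        n0 = rng.uniform(0, 30, size=3)
        A = ap.build_transition_matrix(
            ap.vital_rates_at(c, ap.Covariates(0.0, "A", 0)))
        got = ap.project_interval(n0, c, "A", lambda d: 0, plant, 0, 6)
        np.testing.assert_allclose(got, np.linalg.matrix_power(A, 6) @ n0,
                                   atol=1e-10)

    def test_missing_plant_day_raises(self, truth):
        plant = PlantSizeSeries(0, np.array([5.0, 5.0]))
        with pytest.raises(ValueError, match="plant size undefined"):
            ap.project_interval([1, 1, 1], truth, "A", lambda d: 0,
                                plant, t0=0, dt=3)


class TestPlantInterpolation:
    def test_single_observation_constant(self):
        s = ap.interpolate_plant_size([(0, 10.0)], window=(0, 8))
        assert np.all(s.values == 10.0)

    def test_linear_data_recovered(self):
        s = ap.interpolate_plant_size([(0, 10.0), (10, 20.0)])
        assert s.leaves(5) == pytest.approx(15.0, abs=1e-6)

    def test_smoother_passes_through_collinear_points(self):
        obs = [(d, 5.0 + 2.0 * d) for d in (0, 3, 7, 10, 14, 17, 21)]
        s = ap.interpolate_plant_size(obs)
        for d, v in obs:
            assert s.leaves(d) == pytest.approx(v, rel=1e-6)

    def test_clamped_at_one_leaf(self):
        s = ap.interpolate_plant_size(
            [(0, 1.0), (3, 30.0), (7, 1.0), (10, 40.0), (14, 1.0)])
        assert s.values.min() >= 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ap.interpolate_plant_size([])
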