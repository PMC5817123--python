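import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cannorm.model_selection import (
    akaike_weights,
    build_exploitation_design,
    compare_nonlinear,
    fit_linear_model,
    fit_nonlinear,
    select_largest_cannibal_models,
)

VICTIM_COUNTS = np.array([0, 1, 1, 3, 3, 4, 5, 6, 7, 8, 9], dtype=float)


class TestAkaikeWeights:
    def test_published_nonlinear_pair(self, ):
        w = akaike_weights([244.7364, 244.5961])
        np.testing.assert_allclose(w, [0.4825, 0.5175], atol=5e-5)

    def test_published_six_model_weights(self):
        w = akaike_weights([54.0536, 51.5745, 46.2726, 52.7792, 48.1799, 48.8814])
        np.testing.assert_allclose(
            w, [0.0114, 0.0395, 0.5598, 0.0216, 0.2157, 0.1519], atol=5e-5
        )

    def test_equal_aics_equal_weights(self):
        np.testing.assert_allclose(akaike_weights([10.0, 10.0, 10.0]), 1 / 3)

    def test_weights_decrease_with_aic(self, rng):
        aics = np.sort(rng.uniform(0, 50, 6))
        w = akaike_weights(aics)
        assert np.all(np.diff(w) <= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-1e3, 1e3), st.integers(0, 2**31 - 1))
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        aics = rng.uniform(0, 100, 5)
        np.testing.assert_allclose(
            akaike_weights(aics), akaike_weights(aics + shift), atol=1e-9
        )


class TestNonlinearFits:
    def test_power_curve_parameter_recovery(self):
        """Noise-free data from a power law with the published best-fit
        coefficients is recovered to high precision."""
        a, b, c = -1.0682, 4.5605, 0.2491
        y = a + b * np.where(VICTIM_COUNTS > 0, VICTIM_COUNTS, 1) ** c * (VICTIM_COUNTS > 0)
        fit = fit_nonlinear(VICTIM_COUNTS, y, "power")
        np.testing.assert_allclose(fit.coefficients, [a, b, c], atol=1e-4)
        assert fit.rss < 1e-10
        assert fit.k == 3

    def test_asymptotic_curve_parameter_recovery(self):
        a, b, c = -0.02455, -0.02580, 0.8223
        y = a + b * (1 - np.exp(-c * VICTIM_COUNTS))
        fit = fit_nonlinear(VICTIM_COUNTS, y, "asymptotic")
        np.testing.assert_allclose(fit.coefficients, [a, b, c], atol=1e-4)
        assert fit.rss < 1e-10

    def test_constant_response_flat_curve(self):
        y = np.full_like(VICTIM_COUNTS, 2.5)
        fit = fit_nonlinear(VICTIM_COUNTS, y, "asymptotic")
        pred = fit.coefficients[0] + fit.coefficients[1] * (
            1 - np.exp(-fit.coefficients[2] * VICTIM_COUNTS)
        )
        np.testing.assert_allclose(pred, 2.5, atol=1e-6)

    def test_input_order_invariance(self, rng):
        y = 1 + 2 * VICTIM_COUNTS**0.5 + 0.01 * rng.normal(size=len(VICTIM_COUNTS))
        perm = rng.permutation(len(VICTIM_COUNTS))
        f1 = fit_nonlinear(VICTIM_COUNTS, y, "power")
        f2 = fit_nonlinear(VICTIM_COUNTS[perm], y[perm], "power")
        assert f1.rss == pytest.approx(f2.rss, rel=1e-6)

    def test_selection_consistency_asymptotic_truth(self):
        """With asymptotic-generated data at low noise, the asymptotic form
        wins the AIC comparison in most replicates."""
        rng = np.random.default_rng(31)
        wins = 0
        n_sim = 200
        for _ in range(n_sim):
            y = 0.5 + 2.0 * (1 - np.exp(-0.6 * VICTIM_COUNTS)) + 0.02 * rng.normal(
                size=len(VICTIM_COUNTS)
            )
            cmp_ = compare_nonlinear(VICTIM_COUNTS, y)
            wins += cmp_.best.model == "asymptotic"
        assert wins / n_sim >= 0.90

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            fit_nonlinear([-1, 0, 1, 2], [0, 1, 2, 3], "power")


class TestExploitationDesign:
    @pytest.mark.parametrize(
        "model_id,expected",
        [(1, [1.5]), (2, [1.0]), (3, [3.0]), (4, [2.0]), (5, [2.0, 3.0]), (6, [2.0, 3.0, 6.0])],
    )
    def test_single_population_covariates(self, model_id, expected):
        got = build_exploitation_design([2], [3], model_id)
        np.testing.assert_allclose(got[0], expected)

    def test_model6_includes_product(self):
        got = build_exploitation_design([3], [9], 6)
        np.testing.assert_allclose(got[0], [3, 9, 27])

    def test_model1_requires_positive_cannibals(self):
        with pytest.raises(ValueError, match="x1 > 0"):
            build_exploitation_design([0, 2], [3, 3], 1)


class TestLinearModels:
    def test_zero_noise_coefficient_recovery(self, rng):
        x = rng.normal(size=(12, 2))
        y = 1.5 - 2.0 * x[:, 0] + 0.75 * x[:, 1]
        fit = fit_linear_model(x, y)
        np.testing.assert_allclose(fit.coefficients, [1.5, -2.0, 0.75], atol=1e-10)
        assert fit.k == 3

    def test_rank_deficient_rejected(self, rng):
        x = rng.normal(size=12)
        with pytest.raises(ValueError, match="rank"):
            fit_linear_model(np.column_stack([x, 2 * x]), x)


class TestLargestCannibalSelection:
    X1 = np.array([1, 1, 2, 2, 1, 3, 3, 6, 3, 3], dtype=float)
    X2 = np.array([1, 1, 3, 3, 4, 5, 6, 7, 8, 9], dtype=float)

    def test_exact_exclusive_exploitation_selects_model3(self):
        y = 2.9872 + 0.855 * self.X2  # published best size model, noise-free
        table = select_largest_cannibal_models(self.X1, self.X2, y)
        assert table.best.model.startswith("X3")
        best = [f for f in table.fits if f.model.startswith("X3")][0]
        assert best.rss == pytest.approx(0.0, abs=1e-18)
        assert best.w_aic > 0.5

    def test_pure_interference_exact_prefers_model4(self):
        y = 1.0 + 0.8 * self.X1  # response depends on cannibal count only
        table = select_largest_cannibal_models(self.X1, self.X2, y)
        assert table.best.model.startswith("x1 (")

    def test_pure_interference_noisy_model4_wins_majority(self):
        # AIC over-selects nesting competitors (Models 5/6) with a
        # noise-scale-free probability, so the generating model wins a
        # majority, not near-certainty, under noise
        rng = np.random.default_rng(41)
        wins = 0
        n_sim = 200
        for _ in range(n_sim):
            y = 1.0 + 0.8 * self.X1 + 0.01 * rng.normal(size=len(self.X1))
            table = select_largest_cannibal_models(self.X1, self.X2, y)
            wins += table.best.model.startswith("x1 (")
        assert wins / n_sim > 0.5

    def test_interaction_response_prefers_model6(self):
        rng = np.random.default_rng(42)
        wins = 0
        n_sim = 200
        for _ in range(n_sim):
            y = (
                0.0236
                - 0.01593 * self.X2
                - 0.03813 * self.X1
                + 0.006031 * self.X1 * self.X2
                + 0.001 * rng.normal(size=len(self.X1))
            )
            table = select_largest_cannibal_models(self.X1, self.X2, y)
            wins += table.best.model.startswith("x1 + x2 + x1*x2")
        assert wins / n_sim >= 0.90

    def test_weights_sum_to_one_and_best_delta_zero(self, rng):
        y = rng.normal(size=len(self.X1))
        table = select_largest_cannibal_models(self.X1, self.X2, y)
        assert sum(f.w_aic for f in table.fits) == pytest.approx(1.0, abs=1e-9)
        assert min(f.delta_aic for f in table.fits) == 0.0

    def test_too_few_tanks_rejected(self):
        with pytest.raises(ValueError):
            select_largest_cannibal_models([1, 2, 3], [1, 2, 3], [0.1, 0.2, 0.3])
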