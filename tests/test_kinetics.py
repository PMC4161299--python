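"""Survival curves, mixture fits, state frequencies, tail probabilities."""

import numpy as np
import pytest

from hoptrack import kinetics as kin
from hoptrack.core import TrackSet, Trajectory

DT = 0.033

# reference three-component dissociation parameters (wild type and a
# charge-reduced mutant) used as generators throughout
WT_A = np.array([0.090, 0.294, 0.616])
WT_K = np.array([0.6, 2.6, 15.6])
MUT4_A = np.array([0.023, 0.101, 0.876])
MUT4_K = np.array([0.7, 4.0, 32.8])

WT_DIFF_A = np.array([0.889, 0.102, 0.020])
WT_DIFF_D = np.array([0.017, 0.084, 0.705])
WT_EPS = 0.021


class TestSurvival:
    def test_convention_on_small_example(self):
        # lifetimes of 1, 2 and 3 frames
        curve = kin.survival_from_lifetimes(np.array([1, 2, 3]) * DT, DT)
        assert curve.times == pytest.approx([0, DT, 2 * DT, 3 * DT])
        assert curve.fraction == pytest.approx([1.0, 1.0, 2 / 3, 1 / 3])

    def test_single_frame_lifetimes(self):
        curve = kin.survival_from_lifetimes(np.array([DT, DT]), DT)
        assert curve.fraction == pytest.approx([1.0, 1.0])

    def test_monotone_non_increasing(self, rng):
        lifetimes = rng.exponential(1.0, 500)
        curve = kin.survival_from_lifetimes(lifetimes, DT)
        assert curve.fraction[0] == 1.0
        assert np.all(np.diff(curve.fraction) <= 0)

    def test_simulated_single_exponential(self, no_hop_no_bleach_sim):
        _, tracks = no_hop_no_bleach_sim
        curve = kin.survival_curve(tracks)
        # S(t) ~ exp(-t) at k_off = 1/s; compare at t = 1 s
        idx = np.argmin(np.abs(curve.times - 1.0))
        assert curve.fraction[idx] == pytest.approx(np.exp(-1.0), abs=0.03)


class TestExpMixture:
    def test_pure_single_exponential_exact(self):
        t = np.arange(200) * DT
        curve = kin.SurvivalCurve(t, np.exp(-2.0 * t), np.ones_like(t))
        fit = kin.fit_exp_mixture(curve, 1)
        assert fit.amplitudes[0] == pytest.approx(1.0, abs=1e-4)
        assert fit.rates[0] == pytest.approx(2.0, rel=1e-3)

    def test_recovers_reference_three_component_model(self):
        lifetimes = kin.sample_exp_mixture_lifetimes(WT_A, WT_K, 16088, DT, seed=42)
        curve = kin.survival_from_lifetimes(lifetimes, DT)
        fit = kin.fit_exp_mixture(curve, 3)
        assert fit.rates[0] == pytest.approx(WT_K[0], rel=0.10)
        assert fit.rates[1] == pytest.approx(WT_K[1], rel=0.25)
        assert fit.rates[2] == pytest.approx(WT_K[2], rel=0.25)
        assert fit.amplitudes.sum() == pytest.approx(1.0, abs=0.02)

    def test_overfitting_two_component_data_is_flagged(self):
        t = np.arange(400) * DT
        S = 0.5 * np.exp(-0.5 * t) + 0.5 * np.exp(-5.0 * t)
        curve = kin.SurvivalCurve(t, S, np.ones_like(t))
        fit = kin.fit_exp_mixture(curve, 3)
        assert fit.degenerate

    def test_model_comparison_prefers_single_state_for_single_state(self):
        lifetimes = kin.sample_exp_mixture_lifetimes([1.0], [1.0], 8000, DT, seed=3)
        curve = kin.survival_from_lifetimes(lifetimes, DT)
        rss = kin.compare_exp_models(curve, ns=(1, 2))
        # adding a component must not help beyond noise
        assert rss[2] > rss[1] * 0.5

    def test_too_few_points_raise(self):
        curve = kin.SurvivalCurve(np.arange(5) * DT, np.ones(5), np.ones(5))
        with pytest.raises(ValueError):
            kin.fit_exp_mixture(curve, 3)


class TestStateFrequencies:
    @pytest.mark.parametrize(
        "A,k,expected",
        [
            (WT_A, WT_K, [50, 37, 13]),
            (MUT4_A, MUT4_K, [39, 30, 31]),
            ([1.0], [2.0], [100]),
        ],
    )
    def test_reference_rows(self, A, k, expected):
        fit = kin.ExpMixtureFit(len(k), np.asarray(A, float), np.asarray(k, float), 0.0)
        assert kin.state_frequencies(fit).tolist() == expected

    def test_zero_rate_raises(self):
        fit = kin.ExpMixtureFit(1, np.array([1.0]), np.array([0.0]), 0.0)
        with pytest.raises(ValueError):
            kin.state_frequencies(fit)


class TestDisplacements:
    def test_stationary_spot_all_zero(self):
        ts = TrackSet(
            [Trajectory(0, np.arange(5), np.full(5, 1.0), np.full(5, 2.0))],
            frame_interval=DT,
        )
        assert np.all(kin.displacement_distribution(ts) == 0)

    def test_lag_beyond_length_empty(self):
        ts = TrackSet(
            [Trajectory(0, [0, 1], [0.0, 0.1], [0.0, 0.1])], frame_interval=DT
        )
        assert kin.displacement_distribution(ts, lag=2).size == 0

    def test_simulated_msd(self, default_sim):
        _, tracks = default_sim
        disp = kin.displacement_distribution(tracks)
        D_hat = np.mean(disp**2) / (4 * DT)
        assert D_hat == pytest.approx(0.01, rel=0.1)


class TestDiffusionMixture:
    def test_single_rayleigh_recovery(self, rng):
        disp = kin.sample_displacements([1.0], [0.1], 20000, DT, epsilon=0.0, seed=rng)
        fit = kin.fit_diffusion_mixture(disp, 1, DT, epsilon=0.0)
        assert fit.diffusion_coeffs[0] == pytest.approx(0.1, rel=0.05)

    def test_recovers_reference_three_component_model(self):
        disp = kin.sample_displacements(
            WT_DIFF_A, WT_DIFF_D, 50000, DT, epsilon=WT_EPS, seed=99
        )
        fit = kin.fit_diffusion_mixture(disp, 3, DT, epsilon=WT_EPS)
        assert fit.diffusion_coeffs[0] == pytest.approx(WT_DIFF_D[0], rel=0.20)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert fit.weights[0] == pytest.approx(WT_DIFF_A[0], abs=0.1)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            kin.fit_diffusion_mixture(np.zeros(1000), 1, DT)

    def test_observable_floor(self):
        fit = kin.DiffusionMixtureFit(
            1, np.array([1.0]), np.array([0.1]), 0.021, DT, 0.0
        )
        assert fit.observable_floor == pytest.approx(0.021**2 / DT)

    def test_localization_error_from_msd(self, rng):
        # static particles with pure localization noise: MSD intercept 4*eps^2
        eps = 0.03
        trajs = []
        for i in range(200):
            x = 5.0 + rng.normal(0, eps, 30)
            y = 5.0 + rng.normal(0, eps, 30)
            trajs.append(Trajectory(i, np.arange(30), x, y))
        ts = TrackSet(trajs, frame_interval=DT)
        assert kin.localization_error_from_msd(ts) == pytest.approx(eps, rel=0.15)


class TestTailProbability:
    def test_closed_form_value(self):
        fit = kin.DiffusionMixtureFit(
            1, np.array([1.0]), np.array([0.705]), 0.0, DT, 0.0
        )
        assert kin.tail_probability(fit, 0.45) == pytest.approx(0.1135, abs=0.0005)

    def test_limits(self):
        fit = kin.DiffusionMixtureFit(
            2, np.array([0.6, 0.4]), np.array([0.02, 0.5]), 0.02, DT, 0.0
        )
        assert kin.tail_probability(fit, 0.0) == pytest.approx(1.0)
        assert kin.tail_probability(fit, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_matches_numeric_integration(self):
        fit = kin.DiffusionMixtureFit(
            3, np.array([0.5, 0.3, 0.2]), np.array([0.017, 0.084, 0.705]),
            0.021, DT, 0.0,
        )
        r = np.linspace(0.45, 20.0, 400000)
        numeric = np.trapezoid(fit.pdf(r), r)
        assert kin.tail_probability(fit, 0.45) == pytest.approx(numeric, rel=1e-4)


class TestHoppingLifetime:
    @pytest.mark.parametrize("rate", [42.0, 23.5])
    def test_recovers_reference_rates(self, rate, rng):
        t = np.floor(rng.exponential(1.0 / rate, 1000) / DT) * DT
        _, k = kin.fit_hopping_lifetime(t, DT)
        assert k == pytest.approx(rate, rel=0.12)

    def test_doubling_lifetimes_halves_rate(self, rng):
        t = np.floor(rng.exponential(1.0 / 20.0, 2000) / DT) * DT
        _, k1 = kin.fit_hopping_lifetime(t, DT)
        _, k2 = kin.fit_hopping_lifetime(2 * t, 2 * DT)
        assert k2 == pytest.approx(k1 / 2, rel=0.02)

    def test_all_equal_lifetimes_raise(self):
        with pytest.raises(ValueError):
            kin.fit_hopping_lifetime(np.full(50, DT), DT)
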