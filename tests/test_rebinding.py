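"""Emergence-rate fitting, edge correction and the rebinding estimator."""

import numpy as np
import pytest

from hoptrack import SimConfig, simulate
from hoptrack import kinetics as kin
from hoptrack import rebinding as reb
from hoptrack.core import CellGeometry, TrackSet, Trajectory, geometry_from_mask

DT = 0.033


def uniform_trackset(n, rng, geometry, n_frames=3000, lifetime_frames=1):
    """Single-visit trajectories at uniform positions and times."""
    trajs = []
    if geometry.periodic:
        W, H = geometry.width, geometry.height
    else:
        H, W = (np.array(geometry.mask.shape) * geometry.pixel_size)
    for i in range(n):
        f0 = int(rng.integers(0, n_frames - lifetime_frames))
        x = rng.uniform(0, W)
        y = rng.uniform(0, H)
        frames = np.arange(f0, f0 + lifetime_frames)
        trajs.append(Trajectory(i, frames, np.full(lifetime_frames, x),
                                np.full(lifetime_frames, y)))
    return TrackSet(trajs, frame_interval=DT, n_frames=n_frames, geometry=geometry)


class TestEmergenceRate:
    def test_recovers_bleach_constant(self, default_sim):
        _, tracks = default_sim
        fit = reb.fit_emergence_rate(tracks)
        assert fit.k0 == pytest.approx(0.03, rel=0.15)
        assert fit.rho0 == pytest.approx(1.0, rel=0.10)

    def test_constant_rate_gives_zero_decay(self, rng):
        geom = CellGeometry.periodic_rectangle(10.0, 10.0)
        ts = uniform_trackset(3000, rng, geom)
        fit = reb.fit_emergence_rate(ts)
        assert fit.k0 == pytest.approx(0.0, abs=0.01)

    def test_too_few_events_raise(self, rng):
        geom = CellGeometry.periodic_rectangle(10.0, 10.0)
        ts = uniform_trackset(50, rng, geom)
        with pytest.raises(ValueError, match="too few"):
            reb.fit_emergence_rate(ts)


class TestEdgeFactor:
    def test_closed_form_values(self):
        assert reb.edge_factor(0.0, 1.0) == pytest.approx(0.5)
        assert reb.edge_factor(0.5, 1.0) == pytest.approx(2.0 / 3.0)
        assert reb.edge_factor(1.5, 1.0) == 1.0
        assert reb.edge_factor(1.0, 1.0) == 1.0

    def test_uniform_average_matches_perimeter_formula(self, rng):
        """Mean edge factor over uniform points ~ 1 - l0*r/(pi*S0),
        using integral(arccos(u), u=0..1) = 1."""
        mask = np.ones((200, 200), bool)
        geom = geometry_from_mask(mask, 0.05)  # 10 x 10 um cell
        r = 0.5
        x = rng.uniform(0, 10, 200000)
        y = rng.uniform(0, 10, 200000)
        z = geom.boundary_distance(x, y)
        mean_f = reb.edge_factor(z, r).mean()
        expected = 1.0 - geom.perimeter * r / (np.pi * geom.area)
        assert mean_f == pytest.approx(expected, abs=0.003)


class TestExpectedRecruitment:
    def test_homogeneous_limit(self, rng):
        """k0 = 0 and vanishings far from the edge: both estimators reduce
        to rho0 * 2*pi*r*dr*dt."""
        mask = np.ones((400, 400), bool)
        geom = geometry_from_mask(mask, 0.05)  # 20 x 20 um
        trajs = []
        for i in range(500):
            x, y = rng.uniform(8, 12, 2)  # all > 5 um from any edge
            trajs.append(Trajectory(i, [int(rng.integers(0, 100))], [x], [y]))
        ts = TrackSet(trajs, frame_interval=DT, n_frames=100, geometry=geom)
        rate = reb.EmergenceRateFit(rho0=1.0, k0=0.0)
        r_lo, r_hi = 1.0, 1.05
        emp, closed = reb.expected_recruitment(ts, rate, r_lo, r_hi, DT)
        homog = np.pi * (r_hi**2 - r_lo**2) * DT
        assert emp == pytest.approx(homog, rel=1e-6)
        # closed form keeps the perimeter term ~ l0*r/(pi*S0) ~ 3%
        assert closed == pytest.approx(homog * (1 - geom.perimeter * 1.0 / (np.pi * geom.area)), rel=0.02)

    def test_empirical_matches_closed_form_for_uniform_vanishings(self, rng):
        """Uniformly scattered vanish points on a square cell: the
        empirical arccos sum agrees with the perimeter approximation."""
        mask = np.ones((200, 200), bool)
        geom = geometry_from_mask(mask, 0.05)
        ts = uniform_trackset(3000, rng, geom, n_frames=100)
        rate = reb.EmergenceRateFit(rho0=1.0, k0=0.0)
        emp, closed = reb.expected_recruitment(ts, rate, 0.45, 0.5, DT)
        # 3-sigma Monte-Carlo band estimated from the per-point spread
        assert emp == pytest.approx(closed, rel=0.02)

    def test_invitro_limit(self):
        """l0/S0 -> 0 and k0 -> 0 reduces to the uniform-density form."""
        geom = CellGeometry.periodic_rectangle(10.0, 10.0)
        ts = uniform_trackset(500, np.random.default_rng(0), geom)
        rate = reb.EmergenceRateFit(rho0=2.0, k0=0.0)
        emp, closed = reb.expected_recruitment(ts, rate, 0.0, 1.0, DT)
        assert emp == pytest.approx(2.0 * np.pi * DT, rel=1e-6)
        assert closed == pytest.approx(2.0 * np.pi * DT, rel=1e-6)

    def test_bad_annulus_raises(self, rng):
        geom = CellGeometry.periodic_rectangle(10.0, 10.0)
        ts = uniform_trackset(100, rng, geom)
        rate = reb.EmergenceRateFit(rho0=1.0, k0=0.0)
        with pytest.raises(ValueError):
            reb.expected_recruitment(ts, rate, 1.0, 0.5, DT)


@pytest.fixture(scope="module")
def analyzed_default():
    """Default simulation with all fits prepared."""
    truth, tracks = simulate(SimConfig(), seed=31)
    rate = reb.fit_emergence_rate(tracks)
    disp = kin.displacement_distribution(tracks)
    dfit = kin.fit_diffusion_mixture(disp, 1, DT)
    return truth, tracks, rate, dfit


class TestTemporalProfile:
    def test_mass_in_return_window(self, analyzed_default):
        """With a fixed 66-ms excursion, rebinding mass concentrates in the
        window whose gap equals t_return (vanishing = last observed frame)."""
        truth, tracks, rate, dfit = analyzed_default
        prof = reb.temporal_rebinding(
            tracks, rate, dfit, n_windows=6, r_min_late=0.0
        )
        ret = truth.config.return_frames  # = 2
        assert np.argmax(prof.corrected) == ret
        assert prof.corrected[ret] > 0.01
        others = np.delete(prof.corrected, ret)
        assert np.abs(others).max() < 0.6 * prof.corrected[ret]

    def test_profiles_carry_uncorrected_values(self, analyzed_default):
        _, tracks, rate, dfit = analyzed_default
        prof = reb.temporal_rebinding(tracks, rate, dfit, n_windows=4)
        assert np.all(prof.uncorrected >= prof.corrected)
        assert prof.uncorrected == pytest.approx(
            prof.corrected + prof.recruitment + prof.diffusion_term
        )

    def test_missing_diffusion_fit_raises(self, analyzed_default):
        _, tracks, rate, _ = analyzed_default
        with pytest.raises(ValueError, match="diffusion"):
            reb.temporal_rebinding(tracks, rate, None, n_windows=3)


class TestSpatialProfile:
    def test_null_profile_flat(self, rng):
        cfg = SimConfig(p_reb=0.0)
        _, tracks = simulate(cfg, seed=41)
        rate = reb.fit_emergence_rate(tracks)
        prof = reb.spatial_rebinding(tracks, rate, window=2)
        assert np.abs(prof.corrected).max() < 0.01
        assert abs(prof.corrected.sum()) < 0.02

    def test_profile_decays_with_distance(self, analyzed_default):
        """Hop displacements follow the 66-ms cytosolic Gaussian, so the
        spatial profile is maximal near the inner radius and ~0 by 2 um."""
        _, tracks, rate, dfit = analyzed_default
        prof = reb.spatial_rebinding(tracks, rate, window=2, r_min=0.0)
        inner = prof.corrected[prof.bins < 0.6].sum()
        outer = prof.corrected[prof.bins > 1.5].sum()
        assert inner > 10 * abs(outer)

    def test_integral_consistent_with_temporal_window(self, analyzed_default):
        _, tracks, rate, dfit = analyzed_default
        prof = reb.spatial_rebinding(tracks, rate, window=2, delta_r=0.05)
        total = reb.temporal_rebinding(
            tracks, rate, dfit, n_windows=3
        ).corrected[2]
        assert prof.corrected.sum() == pytest.approx(total, abs=1e-3)


class TestRebindingProbability:
    def test_null_simulations_cover_zero(self):
        values = []
        for seed in range(8):
            cfg = SimConfig(p_reb=0.0, n_steps=1500)
            _, tracks = simulate(cfg, seed=100 + seed)
            rate = reb.fit_emergence_rate(tracks)
            disp = kin.displacement_distribution(tracks)
            dfit = kin.fit_diffusion_mixture(disp, 1, DT)
            values.append(
                reb.rebinding_scalar(tracks, rate, dfit, r_min_late=0.0)
            )
        values = np.array(values)
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean()) < 2 * se + 1e-3

    def test_identical_cells_have_zero_ci_width(self):
        result = reb.aggregate_rebinding(np.array([0.05, 0.05, 0.05]))
        assert result.mean == pytest.approx(0.05)
        assert result.ci_high - result.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_ttest_against_reference_group(self, rng):
        wild_type = rng.normal(0.08, 0.01, 8)
        mutant = rng.normal(0.15, 0.01, 8)
        result = reb.aggregate_rebinding(mutant, reference=wild_type)
        assert result.p_value < 1e-4
        same = reb.aggregate_rebinding(wild_type, reference=wild_type)
        assert same.p_value == pytest.approx(1.0)
        # CI should cover the true mean
        assert result.ci_low < 0.15 < result.ci_high

    def test_single_trial_recovery(self, analyzed_default):
        truth, tracks, rate, dfit = analyzed_default
        p = reb.rebinding_scalar(
            tracks, rate, dfit, t_min=2 * DT, t_max=3 * DT, r_min_late=0.0
        )
        assert p == pytest.approx(truth.config.p_reb, abs=0.03)


class TestInVitro:
    def test_uniform_emergences_give_zero(self, rng):
        geom = CellGeometry.periodic_rectangle(30.0, 30.0)
        ts = uniform_trackset(4000, rng, geom, n_frames=3000)
        p = reb.invitro_rebinding(ts, R0=2.0, t_max=0.133)
        assert p == pytest.approx(0.0, abs=0.01)

    def test_equals_invivo_when_no_bleach_no_boundary(self, rng):
        geom = CellGeometry.periodic_rectangle(20.0, 20.0)
        ts = uniform_trackset(3000, rng, geom, n_frames=3000)
        N0, S0, T0 = ts.N0, geom.area, ts.total_time
        rate = reb.EmergenceRateFit(rho0=N0 / (S0 * T0), k0=0.0)
        dfit = kin.DiffusionMixtureFit(
            1, np.array([1.0]), np.array([1e-6]), 0.0, DT, 0.0
        )
        p_vivo = reb.rebinding_scalar(
            ts, rate, dfit, r_min=0.45, r_max=2.0, t_max=0.133
        )
        p_vitro = reb.invitro_rebinding(ts, R0=2.0, t_max=0.133, r_min=0.45)
        assert p_vivo == pytest.approx(p_vitro, abs=1e-9)

    def test_supported_bilayer_scenario_recovers_hop_probability(self):
        # sparse, long, bleach-free observation as on a supported bilayer;
        # at high densities linking absorption would bias the raw counts
        cfg = SimConfig(association_rate=0.1, k_bleach=0.0, n_steps=12000)
        truth, tracks = simulate(cfg, seed=55)
        p = reb.invitro_rebinding(tracks, R0=2.0, t_max=0.133, r_min=0.0)
        assert p == pytest.approx(cfg.p_reb, abs=0.02)
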