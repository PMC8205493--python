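"""Activity parameter, MSD, Van Hove, velocity autocorrelation, overlap/chi4."""

import numpy as np
import pytest

from junctionmech import (
    MsdRegime,
    ValidationError,
    activity_parameter,
    classify_msd_regime,
    mean_squared_displacement,
    self_overlap,
    van_hove,
    velocity_autocorrelation,
)

from conftest import brownian_track, make_recording, make_track, ou_track_2d


class TestActivityParameter:
    def test_stationary_vertex_zero(self):
        rec = make_recording(np.zeros((5, 2)), np.tile([10.0, 0.0], (5, 1)))
        act = activity_parameter(rec)
        assert act.activity_a == 0.0
        assert act.active_vertex_id == "b" or act.tie  # b moved as much (not at all)

    def test_arithmetic(self):
        pos_a = np.zeros((5, 2))
        pos_a[-1] = [2.0, 0.0]  # net displacement 2 μm
        rec = make_recording(pos_a, np.tile([10.0, 0.0], (5, 1)))
        act = activity_parameter(rec)
        assert act.activity_a == pytest.approx(0.2)
        assert act.active_vertex_id == "a"
        assert act.passive_vertex_id == "b"

    def test_rigid_motion_invariance(self, rng):
        pos_a = rng.normal(0, 1, (6, 2))
        pos_b = rng.normal(8, 1, (6, 2))
        act = activity_parameter(make_recording(pos_a, pos_b))
        theta = 0.77
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([3.0, -7.0])
        act2 = activity_parameter(make_recording(pos_a @ R.T + shift, pos_b @ R.T + shift))
        assert act2.activity_a == pytest.approx(act.activity_a, abs=1e-12)
        assert act2.activity_b == pytest.approx(act.activity_b, abs=1e-12)


class TestMsd:
    def test_ballistic_closed_form(self):
        v = np.array([0.1, 0.05])
        t = 2.0 * np.arange(200)
        track = make_track(np.outer(t, v) / 2.0 * 2.0, dt=2.0)
        curve = mean_squared_displacement(track)
        speed2 = float(v @ v)
        assert np.allclose(curve.msd, speed2 * curve.lags**2, rtol=1e-9)
        assert curve.alpha == pytest.approx(2.0, abs=0.01)

    def test_brownian_exponent(self, rng):
        track = brownian_track(rng, 5000, D=0.01)
        curve = mean_squared_displacement(track)
        assert curve.alpha == pytest.approx(1.0, abs=0.05)
        # MSD(Δ) ≈ 4DΔ at small lags
        assert curve.msd[2] == pytest.approx(4 * 0.01 * curve.lags[2], rel=0.15)

    def test_frozen_track(self):
        curve = mean_squared_displacement(make_track(np.ones((50, 2))))
        assert np.allclose(curve.msd, 0.0)
        assert curve.msd[0] == 0.0

    def test_nonuniform_rejected(self):
        times = np.array([0.0, 2.0, 5.0, 6.0])
        track_cls = type(make_track(np.zeros((4, 2))))
        track = track_cls("v", times, np.zeros((4, 2)))
        with pytest.raises(ValidationError, match="resample"):
            mean_squared_displacement(track)

    def test_msd_nonnegative_and_zero_at_origin(self, rng):
        curve = mean_squared_displacement(brownian_track(rng, 300))
        assert curve.msd[0] == 0.0
        assert np.all(curve.msd >= 0)


class TestRegimeClassification:
    def test_ballistic_superdiffusive(self):
        track = make_track(np.outer(np.arange(100), [0.1, 0.0]), dt=2.0)
        assert classify_msd_regime(mean_squared_displacement(track)) is MsdRegime.SUPERDIFFUSIVE

    def test_confined_ou_caged(self, rng):
        # OU MSD plateaus at twice the stationary variance -> local slope ~ 0
        track = ou_track_2d(rng, 800, k=0.5, sigma_stat=0.2)
        assert classify_msd_regime(mean_squared_displacement(track)) is MsdRegime.SUBDIFFUSIVE_CAGED

    def test_brownian_diffusive(self, rng):
        track = brownian_track(rng, 5000, D=0.01)
        assert classify_msd_regime(mean_squared_displacement(track)) is MsdRegime.DIFFUSIVE


class TestVanHove:
    def test_brownian_gaussian_alpha2(self, rng):
        tracks = [brownian_track(rng, 500, D=0.01, vertex_id=f"t{i}") for i in range(10)]
        res = van_hove(tracks, lag=4.0)
        assert res.non_gaussian_alpha2 == pytest.approx(0.0, abs=0.1)
        assert np.all(res.density >= 0)
        assert np.trapezoid(res.density, res.bin_centers) == pytest.approx(1.0, abs=1e-6)

    def test_frozen_tracks_mass_at_zero(self):
        tracks = [make_track(np.full((300, 2), float(i)), vertex_id=f"f{i}") for i in range(3)]
        res = van_hove(tracks, lag=2.0)
        nonzero_bins = res.bin_centers[res.density > 0]
        assert np.all(np.abs(nonzero_bins) < 1e-9)

    def test_two_population_mixture_fat_tails(self, rng):
        # caged-with-hops: mostly small steps, occasional large ones
        tracks = []
        for i in range(10):
            small = rng.normal(0, 0.05, (300, 2))
            hops = rng.random((300, 2)) < 0.03
            steps = np.where(hops, rng.normal(0, 0.6, (300, 2)), small)
            tracks.append(make_track(np.cumsum(steps, axis=0), vertex_id=f"m{i}"))
        res = van_hove(tracks, lag=2.0)
        assert res.non_gaussian_alpha2 > 0.3

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError, match="200"):
            van_hove([brownian_track(rng, 20)], lag=2.0)


class TestVelocityAutocorrelation:
    def test_ballistic_is_unity(self):
        track = make_track(np.outer(np.arange(100), [0.1, 0.02]), dt=2.0)
        lags, cv = velocity_autocorrelation(track, max_lag=20.0)
        assert np.allclose(cv, 1.0, atol=1e-9)

    def test_white_noise_steps_uncorrelated(self, rng):
        n = 4000
        track = make_track(np.cumsum(rng.normal(0, 0.1, (n, 2)), axis=0))
        lags, cv = velocity_autocorrelation(track, max_lag=20.0)
        assert np.all(np.abs(cv[1:]) < 3 / np.sqrt(n))

    def test_confined_ou_anti_persistent_dip(self, rng):
        track = ou_track_2d(rng, 3000, k=0.5, sigma_stat=0.2)
        lags, cv = velocity_autocorrelation(track, max_lag=10.0)
        assert cv[1] < 0  # successive displacements anticorrelate in confinement


class TestSelfOverlap:
    def test_immobile_ensemble(self):
        tracks = [make_track(np.full((100, 2), float(i)), vertex_id=f"i{i}") for i in range(6)]
        res = self_overlap(tracks, cutoff_a=0.2)
        assert np.allclose(res.Q, 1.0)
        assert np.allclose(res.chi4, 0.0)

    def test_brownian_matches_closed_form(self, rng):
        # P(|2D Gaussian displacement| < a) = 1 - exp(-a^2 / (4 D t))
        D, a, N = 0.005, 0.2, 60
        tracks = [brownian_track(rng, 400, D=D, vertex_id=f"b{i}") for i in range(N)]
        res = self_overlap(tracks, cutoff_a=a)
        for k in (2, 5, 10, 25):
            t = res.times[k]
            p = 1 - np.exp(-(a**2) / (4 * D * t))
            tol = 3 * np.sqrt(p * (1 - p) / N)
            assert abs(res.Q[k] - p) < tol
        assert np.all(np.diff(res.Q[1:20]) <= 1e-9)  # monotone decay region
        assert res.Q[0] == 1.0
        assert np.all((res.Q >= 0) & (res.Q <= 1))
        assert np.all(res.chi4 >= 0)

    def test_caged_with_hops_chi4_interior_maximum(self):
        from junctionmech import GeneratorConfig, gen_caged_track

        cfg = GeneratorConfig(duration=800.0, hop_rate=0.01, seed=7)
        tracks = [
            gen_caged_track(cfg, vertex_id=f"c{i}", stream=100 + i) for i in range(40)
        ]
        # cutoff above the cage spread but at the hop scale: overlap is lost
        # through discrete hops, whose staggering across the ensemble is the
        # dynamic heterogeneity chi4 measures
        res = self_overlap(tracks, cutoff_a=0.45)
        peak = int(np.argmax(res.chi4))
        assert 0 < peak < res.chi4.size - 1
        assert res.chi4[peak] > 2 * res.chi4[1]

    def test_small_ensemble_rejected(self, rng):
        with pytest.raises(ValidationError):
            self_overlap([brownian_track(rng, 50)], cutoff_a=0.2)
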