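"""Spatial autocorrelation, cluster-size extraction, spatial order,
vertex-region sizing, and length/cluster cross-correlation."""

import numpy as np
import pytest
from scipy.stats import ttest_rel

from junctionmech import (
    GeneratorConfig,
    IntensityProfileSeries,
    PulseSet,
    SpatialOrder,
    ValidationError,
    cluster_size_exponential_fit,
    cluster_size_series,
    gen_clustered_profile_series,
    intensity_fluctuations,
    length_cluster_crosscorrelation,
    spatial_autocorrelation,
    spatial_order_test,
    vertex_region_cluster_size,
)


def _series_from_frames(frames, pixel_size=0.1, dt=2.0, junction_id="j"):
    frames = np.atleast_2d(np.asarray(frames, float))
    x = pixel_size * np.arange(frames.shape[1])
    return IntensityProfileSeries(
        junction_id, dt * np.arange(frames.shape[0]), x, frames,
        np.tile([x[0], x[-1]], (frames.shape[0], 1)),
    )


class TestFluctuations:
    def test_constant_profile_flagged(self):
        dI, flat = intensity_fluctuations(np.full(32, 7.0))
        assert flat
        assert np.allclose(dI, 0.0)

    def test_mean_plus_sine_recovered(self):
        x = np.arange(64)
        sine = np.sin(2 * np.pi * x / 16)
        dI, flat = intensity_fluctuations(5.0 + sine)
        assert not flat
        assert np.allclose(dI, sine, atol=1e-12)

    def test_zero_mean(self, rng):
        dI, _ = intensity_fluctuations(rng.normal(3, 1, 128))
        assert abs(dI.mean()) < 1e-12


class TestSpatialAutocorrelation:
    def test_white_noise_decorrelates_immediately(self, rng):
        curve = spatial_autocorrelation(rng.normal(0, 1, (200, 200)), pixel_size=0.1)
        assert curve.C[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.abs(curve.C[1:]) < 0.05)
        assert curve.zero_crossing is not None and curve.zero_crossing <= 0.1

    def test_sinusoid_closed_form(self):
        p = 2.0  # μm period
        x = 0.1 * np.arange(400)
        profile = 3.0 + np.sin(2 * np.pi * x / p)
        curve = spatial_autocorrelation(profile[None, :], pixel_size=0.1, max_r=4.0)
        k = np.arange(curve.C.size)
        taper = 1 - k / 400  # biased-estimator taper
        assert np.allclose(curve.C, taper * np.cos(2 * np.pi * curve.r / p), atol=0.02)
        assert curve.zero_crossing == pytest.approx(p / 4, abs=0.1)

    def test_affine_intensity_invariance(self, rng):
        frames = rng.normal(2, 0.5, (10, 150))
        c1 = spatial_autocorrelation(frames, pixel_size=0.1)
        c2 = spatial_autocorrelation(4.2 * frames + 17.0, pixel_size=0.1)
        assert np.allclose(c1.C, c2.C, atol=1e-9)

    def test_reversal_invariance(self):
        cfg = GeneratorConfig(seed=3)
        series = gen_clustered_profile_series(cfg, "clustered", n_frames=20)
        c1 = spatial_autocorrelation(series)
        c2 = spatial_autocorrelation(series.profiles[:, ::-1], pixel_size=0.1)
        assert c1.zero_crossing == pytest.approx(c2.zero_crossing, abs=1e-9)

    def test_all_constant_frames_rejected(self):
        with pytest.raises(ValidationError):
            spatial_autocorrelation(np.ones((5, 100)), pixel_size=0.1)


class TestExponentialFit:
    def test_noiseless_self_consistency(self):
        r = 0.1 * np.arange(30)
        lam, r2 = cluster_size_exponential_fit(r, np.exp(-r / 0.5))
        assert lam == pytest.approx(0.5, abs=0.01)
        assert r2 > 0.999

    def test_flat_curve_flagged(self):
        r = 0.1 * np.arange(30)
        lam, r2 = cluster_size_exponential_fit(r, np.full(30, 0.8))
        assert r2 < 0.5 or lam is None

    def test_noisy_median_recovery(self, rng):
        r = 0.1 * np.arange(25)
        truth = np.exp(-r / 0.6)
        lams = []
        for _ in range(100):
            lam, _ = cluster_size_exponential_fit(r, truth + rng.normal(0, 0.05, r.size))
            if lam is not None:
                lams.append(lam)
        assert abs(np.median(lams) - 0.6) / 0.6 < 0.10


class TestSpatialOrderTest:
    def test_clustered_generator_ordered(self):
        series = gen_clustered_profile_series(GeneratorConfig(seed=11), "clustered", n_frames=20)
        assert spatial_order_test(spatial_autocorrelation(series)) is SpatialOrder.ORDERED

    def test_diffuse_generator_diffuse(self):
        series = gen_clustered_profile_series(GeneratorConfig(seed=11), "diffuse", n_frames=20)
        assert spatial_order_test(spatial_autocorrelation(series)) is SpatialOrder.DIFFUSE

    def test_rule_applied_exactly(self, rng):
        # classification must equal the stated rule on any curve
        curve = spatial_autocorrelation(rng.normal(0, 1, (50, 150)), pixel_size=0.1)
        expected = (
            SpatialOrder.ORDERED
            if curve.fit_r2 >= 0.9 and curve.zero_crossing is not None
            else SpatialOrder.DIFFUSE
        )
        assert spatial_order_test(curve) is expected


class TestClusterSizeSeries:
    def test_run_threshold_arithmetic(self):
        frames = np.zeros((10, 200))
        frames[:, 40:50] = 1.0
        frames[:, 120:130] = 1.0  # two 10-pixel runs at 0.1 μm/pixel
        series = cluster_size_series(_series_from_frames(frames), method="run_threshold")
        assert np.allclose(series.mean_cluster_size, 1.0)

    def test_alternating_scales_tracked(self):
        cfg = GeneratorConfig(seed=21)
        scales = np.where(np.arange(40) % 2 == 0, 0.5, 1.0)
        series = gen_clustered_profile_series(cfg, "clustered", scale_series=scales)
        sizes = cluster_size_series(series).mean_cluster_size
        small = np.nanmedian(sizes[::2])
        large = np.nanmedian(sizes[1::2])
        assert large > small
        assert large / small == pytest.approx(2.0, rel=0.35)

    def test_constant_frames_error(self):
        with pytest.raises(ValidationError):
            cluster_size_series(_series_from_frames(np.ones((12, 100))))


class TestVertexRegion:
    def _pulses(self):
        return PulseSet(((0.0, 80.0),), 10.0, 0.01)

    def test_asymmetric_seeding_recovered(self):
        wins = 0
        for seed in range(50):
            cfg = GeneratorConfig(seed=1000 + seed)
            series = gen_clustered_profile_series(
                cfg, "clustered", n_frames=30, end_scales=(1.2, 0.6)
            )
            sizes = vertex_region_cluster_size(series, self._pulses())
            if sizes["vertex_a"] and sizes["vertex_b"] and sizes["vertex_a"] > sizes["vertex_b"]:
                wins += 1
        assert wins >= 45  # >= 90% of replicates

    def test_symmetric_seeding_null_calibrated(self):
        ok = 0
        for batch in range(10):
            a_sizes, b_sizes = [], []
            for j in range(20):
                cfg = GeneratorConfig(seed=5000 + 100 * batch + j)
                series = gen_clustered_profile_series(cfg, "clustered", n_frames=15)
                sizes = vertex_region_cluster_size(series, self._pulses())
                a_sizes.append(sizes["vertex_a"])
                b_sizes.append(sizes["vertex_b"])
            p = ttest_rel(a_sizes, b_sizes).pvalue
            ok += p > 0.05
        assert ok >= 9  # no spurious asymmetry in >= 90% of batches

    def test_region_exceeding_junction_rejected(self):
        cfg = GeneratorConfig(seed=2, junction_length=4.0)
        series = gen_clustered_profile_series(cfg, "clustered", n_frames=12)
        with pytest.raises(ValidationError):
            vertex_region_cluster_size(series, self._pulses(), region=5.0)


class TestCrossCorrelation:
    def test_shifted_copy_peak_at_programmed_lag(self, rng):
        t = 2.0 * np.arange(300)
        L = np.cumsum(rng.normal(0, 0.1, t.size))  # smooth random walk
        delta = 14.0
        k = int(delta / 2.0)
        s = -np.roll(L, k)
        s[:k] = np.nan  # shifted copy: s(t) = -L(t - delta)
        res = length_cluster_crosscorrelation(L, s, t, max_lag=60.0)
        assert res.peak_lag == pytest.approx(-delta, abs=2.0)
        assert np.all(np.abs(res.rho) <= 1.0 + 1e-12)

    def test_independent_noise_uncorrelated(self, rng):
        n = 400
        t = 2.0 * np.arange(n)
        res = length_cluster_crosscorrelation(
            rng.normal(0, 1, n), rng.normal(0, 1, n), t, max_lag=50.0
        )
        assert np.max(np.abs(res.rho)) <= 3 / np.sqrt(n)

    def test_lag_symmetry_of_reported_grid(self, rng):
        n = 200
        t = 2.0 * np.arange(n)
        res = length_cluster_crosscorrelation(
            rng.normal(0, 1, n), rng.normal(0, 1, n), t, max_lag=30.0
        )
        assert np.allclose(res.lags, -res.lags[::-1])

    def test_insufficient_overlap_rejected(self, rng):
        t = 2.0 * np.arange(10)
        with pytest.raises(ValidationError):
            length_cluster_crosscorrelation(
                rng.normal(0, 1, 10), np.full(10, np.nan), t, max_lag=10.0
            )
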