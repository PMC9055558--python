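"""Matching observers: error core, grid searches, pooling, reliability."""

import numpy as np
import pytest
from dataclasses import replace

from stereoslant.geometry import Direction, PlaneParams, ViewingGeometry, Window
from stereoslant.observers import (
    LocalEstimateMap,
    ObserverConfig,
    calibrate_reliability,
    combine_slant_estimates,
    lateral_position,
    local_matching,
    matching_error,
    pm_estimate,
    pool_distances,
    pool_slants,
    pooled_estimate,
    prepare_context,
    _eval_global_batch,
)
from stereoslant.prefilter import apply_prefilter, build_lowpass
from stereoslant.stimulus import make_stereo_stimulus, make_texture_spec

from conftest import make_stim


class TestMatchingError:
    def test_identical_images_zero(self):
        img = np.random.default_rng(0).normal(size=(8, 8))
        assert matching_error(img, img, metric="sse") == 0.0
        assert matching_error(img, img, metric="ncorr") == pytest.approx(0.0, abs=1e-12)

    def test_sse_equals_two_loop_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 8))
        b = rng.normal(size=(8, 8))
        mask = rng.random((8, 8)) > 0.3
        want = 0.0
        for i in range(8):
            for j in range(8):
                if mask[i, j]:
                    want += (a[i, j] - b[i, j]) ** 2
        got = matching_error(a, b, valid=mask, metric="sse")
        assert got == pytest.approx(want, rel=1e-12)

    def test_empty_mask_raises(self):
        img = np.zeros((4, 4))
        with pytest.raises(ValueError):
            matching_error(img, img, valid=np.zeros((4, 4), bool))

    def test_error_at_truth_twice_filtered_noise_variance(self, vg):
        """With uncorrelated noise in both eyes, the mean per-pixel squared
        prediction error at the true plane parameters is twice the
        filtered-noise variance."""
        fs = build_lowpass(8.0, vg)
        plane = PlaneParams(30.0, 0.0, 100.0)
        ratios = []
        for seed in range(4):
            spec = make_texture_spec(seed=seed)
            stim = make_stereo_stimulus(spec, plane, vg, 0.175, seed=seed + 50)
            cfg = ObserverConfig(kind="PM")
            ctx = prepare_context(stim, cfg, fs, vg)
            err = _eval_global_batch(
                ctx, np.array([plane.slant]), np.array([plane.intercept_distance])
            )[0]
            ratios.append(err / (2 * ctx.sigma_f**2))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


class TestPMEstimate:
    @pytest.mark.parametrize("slant", [0.0, 12.5, 25.0, 50.0, 60.0])
    def test_zero_noise_recovery_exact_on_grid(self, vg, fs16, slant):
        """Without noise the PM search recovers on-grid truth exactly."""
        stim = make_stim(slant=slant, zeta=99.0, noise=0.0, seed=int(slant), vg=vg)
        est = pm_estimate(stim, ObserverConfig(kind="PM"), fs16, vg)
        assert est.slant == slant
        assert est.intercept_distance == pytest.approx(99.0, abs=1e-9)

    def test_coarse_to_fine_equals_exhaustive(self, vg, fs5):
        """Coarse-to-fine refinement lands on the exhaustive grid argmin
        for seeded noisy stimuli (reduced grid for tractability)."""
        cfg = ObserverConfig(
            kind="PM",
            slant_bounds=(35.0, 65.0),
            slant_step=0.5,
            distance_bounds=(99.0, 101.0),
            distance_step=0.1,
            coarse_slant_step=2.5,
            coarse_distance_step=0.25,
        )
        for seed in range(6):
            stim = make_stim(slant=50.0, zeta=100.0, noise=0.34, seed=seed, vg=vg)
            ex = pm_estimate(stim, cfg, fs5, vg, search="exhaustive")
            cf = pm_estimate(stim, cfg, fs5, vg, search="coarse_to_fine")
            assert cf.slant == ex.slant
            assert cf.intercept_distance == pytest.approx(
                ex.intercept_distance, abs=1e-9
            )

    def test_error_surface_returned(self, vg, fs16):
        stim = make_stim(slant=25.0, zeta=100.0, noise=0.0, seed=3, vg=vg)
        est = pm_estimate(stim, ObserverConfig(kind="PM"), fs16, vg, keep_surface=True)
        surf = est.error_surface
        assert surf is not None
        assert surf.errors.shape == (len(surf.slants), len(surf.distances))
        assert np.isfinite(surf.errors).any()

    def test_normalized_correlation_metric(self, vg, fs16, small_window):
        stim = make_stim(slant=25.0, zeta=99.5, noise=0.0, seed=4, vg=vg,
                         window=small_window)
        cfg = ObserverConfig(kind="PM", error_metric="ncorr",
                             coarse_slant_step=5.0)
        est = pm_estimate(stim, cfg, fs16, vg)
        assert est.slant == pytest.approx(25.0, abs=0.5)

    def test_depth_mode_fixed_slant(self, vg, fs16):
        """With the slant clamped, only the distance is searched."""
        stim = make_stim(slant=44.0, zeta=100.3, noise=0.0, seed=5, vg=vg)
        cfg = ObserverConfig(
            kind="PM", fixed_slant=44.0, distance_bounds=(99.0, 101.0),
            distance_step=0.002, coarse_distance_step=0.1,
        )
        est = pm_estimate(stim, cfg, fs16, vg)
        assert est.slant == 44.0
        assert est.intercept_distance == pytest.approx(100.3, abs=0.002)


class TestLocalMatching:
    def test_lfm_frontoparallel_zero_noise(self, vg, fs16, small_window):
        """All local distances equal the true distance within a grid step."""
        stim = make_stim(slant=0.0, zeta=100.0, noise=0.0, seed=6, vg=vg,
                         window=small_window)
        cfg = ObserverConfig(kind="LFM", patch_width=0.5)
        emap = local_matching(stim, cfg, fs16, vg)
        assert len(emap) >= 4
        np.testing.assert_allclose(emap.distance, 100.0, atol=cfg.distance_step)
        np.testing.assert_array_equal(emap.slant, 0.0)

    def test_lfm_equals_lpm_with_zero_slant_grid(self, vg, fs5, small_window):
        """LFM is exactly LPM restricted to a zero local slant."""
        stim = make_stim(slant=40.0, zeta=99.5, noise=0.34, seed=7, vg=vg,
                         window=small_window)
        lfm = local_matching(
            stim, ObserverConfig(kind="LFM", patch_width=0.5), fs5, vg
        )
        lpm0 = local_matching(
            stim,
            ObserverConfig(kind="LPM", patch_width=0.5, slant_bounds=(0.0, 0.0)),
            fs5, vg,
        )
        np.testing.assert_array_equal(lfm.x, lpm0.x)
        np.testing.assert_allclose(lfm.distance, lpm0.distance, atol=1e-9)
        np.testing.assert_allclose(lfm.match_error, lpm0.match_error, rtol=1e-9)

    def test_lfm_distance_map_lumpier_than_lpm(self, vg, fs16):
        """At a steep slant the frontoparallel assumption misestimates
        local distances: LFM's residuals about the true plane exceed
        LPM's (the lumpiness of the distance map)."""
        var_f, var_p = [], []
        for seed in range(3):
            stim = make_stim(slant=60.0, zeta=99.0, noise=0.0, seed=seed + 30, vg=vg)
            for kind, acc in (("LFM", var_f), ("LPM", var_p)):
                emap = local_matching(
                    stim, ObserverConfig(kind=kind, patch_width=0.5), fs16, vg
                )
                x_lat = lateral_position(emap.x, emap.distance, vg)
                true_z = 99.0 + x_lat * np.tan(np.deg2rad(60.0))
                acc.append(np.mean((emap.distance - true_z) ** 2))
        assert np.mean(var_f) > 2 * np.mean(var_p)

    def test_patch_too_large_raises(self, vg, fs16, small_window):
        stim = make_stim(slant=0.0, noise=0.0, seed=8, vg=vg, window=small_window)
        cfg = ObserverConfig(kind="LFM", patch_width=2.0)
        with pytest.raises(ValueError):
            local_matching(stim, cfg, fs16, vg)

    def test_prediction_direction_symmetry(self, vg, fs5, small_window):
        """Predicting left-from-right or right-from-left gives estimates
        that differ by less than the estimate dispersion."""
        diffs, disp = [], []
        for seed in range(6):
            stim = make_stim(slant=50.0, zeta=100.0, noise=0.34,
                             seed=seed + 60, vg=vg, window=small_window)
            e1 = pm_estimate(stim, ObserverConfig(kind="PM"), fs5, vg)
            e2 = pm_estimate(
                stim, ObserverConfig(kind="PM", direction=Direction.L2R), fs5, vg
            )
            diffs.append(e1.slant - e2.slant)
            disp.append(e1.slant - 50.0)
        assert abs(np.mean(diffs)) < 2 * np.std(disp, ddof=1)


class TestPooling:
    def test_pool_distances_exact_recovery(self, vg):
        x = np.linspace(-0.9, 0.9, 7)
        x_lat = lateral_position(x, np.full(7, 100.0), vg)
        z = 99.3 + x_lat * np.tan(np.deg2rad(37.0))
        # iterate: distances determine lateral positions; use true z
        x_lat = lateral_position(x, z, vg)
        z = 99.3 + x_lat * np.tan(np.deg2rad(37.0))
        emap = LocalEstimateMap(
            x=x, y=np.zeros(7), slant=np.zeros(7), distance=z,
            match_error=np.zeros(7),
        )
        s_hat, zeta_hat = pool_distances(emap, vg)
        assert s_hat == pytest.approx(37.0, abs=0.05)
        assert zeta_hat == pytest.approx(99.3, abs=0.01)

    def test_pool_distances_constant_map(self, vg):
        emap = LocalEstimateMap(
            x=np.linspace(-1, 1, 5), y=np.zeros(5), slant=np.zeros(5),
            distance=np.full(5, 100.0), match_error=np.zeros(5),
        )
        s_hat, zeta_hat = pool_distances(emap, vg)
        assert s_hat == pytest.approx(0.0, abs=1e-9)
        assert zeta_hat == pytest.approx(100.0, abs=1e-9)

    def test_pool_distances_equals_grid_minimization(self, vg):
        """The closed form minimizes the pooling objective: it beats every
        candidate on a dense 2-D grid of (slant, intercept)."""
        rng = np.random.default_rng(9)
        x = np.linspace(-1, 1, 9)
        z = 100.0 + rng.normal(0, 0.5, 9)
        emap = LocalEstimateMap(
            x=x, y=np.zeros(9), slant=np.zeros(9), distance=z,
            match_error=np.zeros(9),
        )
        s_hat, zeta_hat = pool_distances(emap, vg)
        x_lat = lateral_position(x, z, vg)

        def objective(s, zeta):
            return np.sum((z - (zeta + x_lat * np.tan(np.deg2rad(s)))) ** 2)

        best = objective(s_hat, zeta_hat)
        s_grid = np.linspace(-80, 80, 161)
        z_grid = np.linspace(98, 102, 81)
        for s in s_grid:
            for zt in z_grid:
                assert best <= objective(s, zt) + 1e-9

    def test_pool_distances_rank_deficient_raises(self, vg):
        emap = LocalEstimateMap(
            x=np.zeros(4), y=np.linspace(-1, 1, 4), slant=np.zeros(4),
            distance=np.full(4, 100.0), match_error=np.zeros(4),
        )
        with pytest.raises(np.linalg.LinAlgError):
            pool_distances(emap, vg)

    def test_pool_slants_is_mean_and_grid_minimum(self):
        emap = LocalEstimateMap(
            x=np.zeros(2), y=np.zeros(2), slant=np.array([20.0, 40.0]),
            distance=np.full(2, 100.0), match_error=np.zeros(2),
        )
        s = pool_slants(emap)
        assert s == pytest.approx(30.0)
        grid = np.linspace(-80, 80, 3201)
        obj = [(np.sum((emap.slant - g) ** 2), g) for g in grid]
        assert min(obj)[1] == pytest.approx(s, abs=0.1)

    def test_combine_trivial_identities(self):
        assert combine_slant_estimates(10.0, 20.0, 3.0, 1.0) == pytest.approx(12.5)
        assert combine_slant_estimates(10.0, 20.0, 2.0, 2.0) == pytest.approx(15.0)
        assert combine_slant_estimates(10.0, 20.0, 5.0, 0.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            combine_slant_estimates(1.0, 2.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            combine_slant_estimates(1.0, 2.0, -1.0, 2.0)

    def test_combined_estimate_between_cues(self, vg, fs16, small_window):
        stim = make_stim(slant=50.0, zeta=100.0, noise=0.175, seed=10, vg=vg,
                         window=small_window)
        emap = local_matching(
            stim, ObserverConfig(kind="LPM", patch_width=0.5), fs16, vg
        )
        pe = pooled_estimate(emap, vg)
        lo = min(pe.slant_from_distances, pe.slant_from_slants)
        hi = max(pe.slant_from_distances, pe.slant_from_slants)
        assert lo <= pe.slant <= hi
        assert pe.reliability_distances >= 0 and pe.reliability_slants >= 0


class TestReliabilityCalibration:
    def test_gaussian_estimator_reliability(self):
        """An estimator with SD 2 degrees has reliability 1/4 per cue."""

        def simulate(test_slant, seed):
            rng = np.random.default_rng(seed)
            return (test_slant + rng.normal(0, 2.0), test_slant + rng.normal(0, 2.0))

        cal = calibrate_reliability(
            simulate, reference_slant=25.0,
            test_slants=[20.0, 25.0, 30.0], n_sims=400, seed=0,
        )
        assert cal.r_z == pytest.approx(0.25, rel=0.15)
        assert cal.r_s == pytest.approx(0.25, rel=0.15)

    def test_pure_bias_removed(self):
        """A multiplicatively biased estimator is unbiased after bias
        correction: residual means vanish."""

        def simulate(test_slant, seed):
            rng = np.random.default_rng(seed)
            v = 0.8 * test_slant + rng.normal(0, 0.5)
            return (v, v)

        cal = calibrate_reliability(
            simulate, reference_slant=25.0,
            test_slants=[20.0, 25.0, 30.0], n_sims=300, seed=1,
        )
        expected_bias = 0.8 * np.array([20.0, 25.0, 30.0]) - np.array(
            [20.0, 25.0, 30.0]
        )
        np.testing.assert_allclose(cal.bias_distances, expected_bias, atol=0.15)
        assert cal.r_z > 0

    def test_zero_dispersion_capped(self):
        def simulate(test_slant, seed):
            return (test_slant, test_slant)

        cal = calibrate_reliability(
            simulate, 0.0, [0.0, 5.0], n_sims=20, seed=2, reliability_cap=1e4
        )
        assert cal.r_z == 1e4
        assert cal.r_s == 1e4
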