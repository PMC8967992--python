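"""Simulator: point sampling, rendering, camera model, SPB channel, grids."""

import math

import numpy as np
import pytest
from scipy import stats

from npcquant.gaussian import fit_gaussian_1d
from npcquant.simulate import (FociTruth, PackingError, SimConfig,
                               apply_camera, generate_condition_grid,
                               generate_nucleolar_scene, render_volume,
                               sample_points_on_sphere, sample_spb_pair,
                               simulate_nucleus, sphere_area_um2)

from oracles import brute_force_pairwise_min


class TestSampling:
    def test_single_point_lies_on_sphere(self):
        cfg = SimConfig(radius_nm=1250.0, n_npcs=1, seed=0)
        truth = sample_points_on_sphere(cfg)
        r = np.linalg.norm(truth.positions_nm[0] - truth.sphere_center_nm)
        assert r == pytest.approx(1250.0, abs=1e-6)

    def test_min_spacing_enforced_brute_force(self):
        cfg = SimConfig(radius_nm=1250.0, n_npcs=125, min_spacing_nm=100.0, seed=1)
        truth = sample_points_on_sphere(cfg)
        assert truth.n == 125
        assert brute_force_pairwise_min(truth.positions_nm) >= 100.0
        radii = np.linalg.norm(truth.positions_nm - truth.sphere_center_nm, axis=1)
        np.testing.assert_allclose(radii, 1250.0, atol=1e-6)

    def test_standard_nucleus_density(self):
        # 125 pores on a 1.25 um sphere: the standard mid-G2-like density
        cfg = SimConfig(radius_nm=1250.0, n_npcs=125, seed=0)
        truth = sample_points_on_sphere(cfg)
        assert round(truth.true_density_per_um2, 1) == 6.4

    def test_z_coordinates_uniform(self):
        # uniform-on-sphere implies z ~ U(-r, r); KS at alpha = 0.01
        cfg = SimConfig(radius_nm=1000.0, n_npcs=10_000, min_spacing_nm=0.0, seed=7)
        truth = sample_points_on_sphere(cfg)
        z = truth.positions_nm[:, 2] - truth.sphere_center_nm[2]
        res = stats.kstest(z, stats.uniform(loc=-1000.0, scale=2000.0).cdf)
        assert res.pvalue > 0.01

    def test_infeasible_packing_raises_with_count(self):
        cfg = SimConfig(radius_nm=500.0, n_npcs=380, min_spacing_nm=100.0, seed=0)
        with pytest.raises(PackingError, match=r"placed only \d+/380"):
            sample_points_on_sphere(cfg, max_attempts_per_point=200)

    def test_config_requires_exactly_one_count_spec(self):
        with pytest.raises(ValueError):
            SimConfig(n_npcs=10, density_per_um2=5.0)
        with pytest.raises(ValueError):
            SimConfig()

    def test_density_resolves_to_count(self):
        cfg = SimConfig(radius_nm=1250.0, density_per_um2=6.4, seed=0)
        assert cfg.resolved_n_npcs() == round(6.4 * sphere_area_um2(1250.0))


class TestRendering:
    def test_empty_truth_renders_zeros(self):
        cfg = SimConfig(n_npcs=0, seed=0)
        truth = FociTruth(np.empty((0, 3)), np.empty(0), np.zeros(3), 1250.0)
        vol = render_volume(truth, cfg)
        assert vol.voxels.shape[0] > 0 and not vol.voxels.any()

    def test_peak_value_at_voxel_centre(self, noiseless_single_emitter):
        _, _, vol, (iz, iy, ix) = noiseless_single_emitter
        assert vol.voxels[iz, iy, ix] == pytest.approx(100.0, abs=1e-9)
        assert vol.voxels.max() == pytest.approx(100.0, abs=1e-9)

    def test_lateral_fwhm_is_psf_fwhm(self, noiseless_single_emitter):
        cfg, _, vol, (iz, iy, ix) = noiseless_single_emitter
        prof = vol.voxels[iz, iy, :]
        pos = (np.arange(len(prof)) + 0.5) * cfg.pixel_nm
        fit = fit_gaussian_1d(pos, prof)
        assert fit.converged
        assert fit.fwhm_nm == pytest.approx(100.0, abs=2.0)

    def test_energy_conservation(self, noiseless_single_emitter):
        cfg, truth, vol, _ = noiseless_single_emitter
        expected = (truth.intensities.sum() * (2 * np.pi) ** 1.5
                    * cfg.sigma_xy_nm**2 * cfg.sigma_z_nm
                    / (cfg.pixel_nm**2 * cfg.zstep_nm))
        assert vol.voxels.sum() == pytest.approx(expected, rel=0.01)

    def test_grid_size_cap(self):
        cfg = SimConfig(radius_nm=1250.0, n_npcs=1, seed=0)
        truth = FociTruth(np.zeros((1, 3)), np.array([1.0]), np.zeros(3), 1250.0)
        with pytest.raises(ValueError, match="exceeds cap"):
            render_volume(truth, cfg, max_voxels=1000)


class TestCamera:
    def test_zero_in_zero_out(self):
        cfg = SimConfig(n_npcs=1, seed=0, read_noise_sd=0.0, shot_noise=False)
        truth = FociTruth(np.empty((0, 3)), np.empty(0), np.zeros(3), 1250.0)
        vol = render_volume(truth, cfg)
        out = apply_camera(vol, cfg)
        assert not out.voxels.any()

    def test_gain_without_noise(self):
        cfg = SimConfig(n_npcs=1, seed=0, gain=20.0, read_noise_sd=0.0,
                        shot_noise=False)
        vol = render_volume(
            FociTruth(np.empty((0, 3)), np.empty(0), np.zeros(3), 1250.0), cfg)
        out = apply_camera(vol.with_voxels(np.full_like(vol.voxels, 100.0)), cfg)
        assert np.all(out.voxels == 2000.0)

    def test_shot_noise_mean_matches_poisson(self):
        # CLT bound: per-voxel var = gain^2 * 100 + read^2
        cfg = SimConfig(n_npcs=1, seed=3, gain=20.0, read_noise_sd=40.0,
                        shot_noise=True)
        n = 100_000
        img = np.full((10, 100, 100), 100.0)
        from npcquant.volume import VolumeImage
        out = apply_camera(VolumeImage(img, 40.0, 125.0), cfg)
        se = math.sqrt(20.0**2 * 100.0 + 40.0**2) / math.sqrt(n)
        assert abs(out.voxels.mean() - 2000.0) < 3 * se

    def test_negative_photons_rejected(self):
        cfg = SimConfig(n_npcs=1, seed=0)
        from npcquant.volume import VolumeImage
        with pytest.raises(ValueError):
            apply_camera(VolumeImage(np.full((2, 2, 2), -1.0), 40, 125), cfg)


class TestSPBChannel:
    def test_separation_is_180(self):
        cfg = SimConfig(n_npcs=125, seed=5)
        spb = sample_spb_pair(cfg)
        assert spb.separation_nm == pytest.approx(180.0, abs=1e-6)

    def test_projected_edge_margin(self):
        # both spots' projected distance to the projected rim >= 400 nm
        cfg = SimConfig(n_npcs=125, seed=6)
        truth = sample_points_on_sphere(cfg)
        for seed in range(10):
            spb = sample_spb_pair(SimConfig(n_npcs=125, seed=seed))
            for p in (spb.mother_nm, spb.daughter_nm):
                lat = np.hypot(p[0] - truth.sphere_center_nm[0],
                               p[1] - truth.sphere_center_nm[1])
                assert cfg.radius_nm - lat >= 400.0

    def test_deterministic_under_seeding(self):
        cfg = SimConfig(n_npcs=125, seed=9)
        a = sample_spb_pair(cfg)
        b = sample_spb_pair(cfg)
        np.testing.assert_array_equal(a.mother_nm, b.mother_nm)
        np.testing.assert_array_equal(a.daughter_nm, b.daughter_nm)

    def test_small_radius_fails_margin(self):
        with pytest.raises(ValueError, match="edge margin"):
            sample_spb_pair(SimConfig(radius_nm=450.0, n_npcs=10, seed=0))


class TestSeeding:
    def test_identical_config_bitwise_identical_volume(self):
        a = simulate_nucleus(SimConfig(n_npcs=50, seed=123))
        b = simulate_nucleus(SimConfig(n_npcs=50, seed=123))
        np.testing.assert_array_equal(a[1].voxels, b[1].voxels)
        np.testing.assert_array_equal(a[0].positions_nm, b[0].positions_nm)


class TestConditionGrid:
    def test_surface_areas_of_extreme_radii(self):
        m = generate_condition_grid([600.0, 1800.0], [1.0], 1, seed=0)
        sa = dict(zip(m.radius_nm, m.true_sa_um2))
        assert sa[600.0] == pytest.approx(4.52, abs=0.005)
        assert sa[1800.0] == pytest.approx(40.7, abs=0.05)

    def test_grid_shape_and_truth_density(self):
        m = generate_condition_grid([1000.0, 1250.0], [4.0, 8.0], 3, seed=1)
        assert len(m) == 12
        np.testing.assert_allclose(m.true_density_per_um2,
                                   m.n_npcs / m.true_sa_um2)
        assert m.seed.nunique() == 12

    def test_manifest_deterministic(self):
        a = generate_condition_grid([1000.0], [4.0], 2, seed=5)
        b = generate_condition_grid([1000.0], [4.0], 2, seed=5)
        assert a.equals(b)


class TestNucleolarScene:
    def test_zero_reduction_flat_profile(self):
        scene = generate_nucleolar_scene(nup_reduction_frac=0.0, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(scene.nup, 1.0)

    def test_reduction_scales_arc_exactly(self):
        scene = generate_nucleolar_scene(nup_reduction_frac=0.2, noise_sd=0.0, seed=1)
        vals = np.unique(scene.nup)
        np.testing.assert_allclose(vals, [0.8, 1.0])
        # reduced samples are exactly the marker's above-half-max run
        reduced = scene.nup < 0.9
        above_half = scene.marker > 0.5 * scene.marker.max()
        # boundary samples may differ by discretisation of the arc edge
        assert (reduced != above_half).sum() <= 4

    def test_invalid_reduction_rejected(self):
        with pytest.raises(ValueError):
            generate_nucleolar_scene(nup_reduction_frac=1.5)
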