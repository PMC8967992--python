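"""SPB-pair fitting, realignment, averaging, axis profiles, exclusion calls."""

import math

import numpy as np
import pytest

from npcquant import spa
from npcquant.detect import FociSet
from npcquant.gaussian import FWHM_FACTOR
from npcquant.segment import NucleusMask
from npcquant.simulate import (FociTruth, SimConfig, apply_camera,
                               render_volume, sample_spb_pair)
from npcquant.volume import VolumeImage


def render_pair(cfg, mother, daughter, noise=False, amps=(100.0, 70.0)):
    truth = FociTruth(np.stack([mother, daughter]), np.array(amps),
                      np.zeros(3), cfg.radius_nm)
    vol = render_volume(truth, cfg)
    if noise:
        vol = apply_camera(vol, cfg, cfg.rng())
    return vol


@pytest.fixture(scope="module")
def centred_pair():
    cfg = SimConfig(radius_nm=1250.0, n_npcs=2, seed=0)
    from npcquant.simulate import _grid_geometry
    _, center = _grid_geometry(cfg)
    mother = center + np.array([-90.0, 0.0, 0.0])
    daughter = center + np.array([90.0, 0.0, 0.0])
    return cfg, mother, daughter


class TestFitSPBPair:
    def test_noiseless_pair_recovers_separation(self, centred_pair):
        cfg, mother, daughter = centred_pair
        vol = render_pair(cfg, mother, daughter)
        pair = spa.fit_spb_pair(vol, np.stack([mother + 25, daughter - 25]))
        assert pair.separation_nm == pytest.approx(180.0, abs=5.0)
        assert pair.mother_amplitude > pair.daughter_amplitude
        np.testing.assert_allclose(pair.mother_nm, mother, atol=5.0)

    def test_duplicate_seeds_on_single_spot_fail(self, centred_pair):
        cfg, mother, _ = centred_pair
        truth = FociTruth(mother[None, :], np.array([100.0]), np.zeros(3), 1250.0)
        vol = render_volume(truth, cfg)
        with pytest.raises(spa.SPBFitError):
            spa.fit_spb_pair(vol, np.stack([mother, mother]))

    def test_noisy_replicates_unbiased(self):
        from npcquant.experiments import spb_separation_recovery
        seps = spb_separation_recovery(n_replicates=15, seed=3)
        se = seps.std(ddof=1) / math.sqrt(len(seps))
        assert abs(seps.mean() - 180.0) < 3 * se


class TestEdgeFilter:
    def _disk_mask(self, r_px=32, size=128):
        yy, xx = np.indices((size, size))
        m = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= r_px**2
        return NucleusMask(m, (0, 0, size, size))

    def _pair_at(self, x_nm, y_nm):
        c = np.array([x_nm, y_nm, 0.0])
        return spa.SPBPair(c, c + np.array([1.0, 0, 0]), 1.0, 0.5, 40.0, 120.0, 0.0)

    def test_centre_of_disk_passes(self):
        mask = self._disk_mask(r_px=32)  # radius 1280 nm at 40 nm px
        pair = self._pair_at(64 * 40.0, 64 * 40.0)
        assert spa.edge_filter(pair, mask, pixel_nm=40.0)

    def test_300nm_from_boundary_fails(self):
        mask = self._disk_mask(r_px=32)
        pair = self._pair_at((64 + 32) * 40.0 - 300.0, 64 * 40.0)
        assert not spa.edge_filter(pair, mask, pixel_nm=40.0)

    def test_outside_mask_fails(self):
        mask = self._disk_mask(r_px=10)
        assert not spa.edge_filter(self._pair_at(0.0, 0.0), mask, pixel_nm=40.0)

    def test_zero_margin_passes_interior(self):
        mask = self._disk_mask(r_px=32)
        pair = self._pair_at((64 + 30) * 40.0, 64 * 40.0)
        assert spa.edge_filter(pair, mask, pixel_nm=40.0, min_nm=0.0)


class TestRealign:
    def test_identity_when_already_aligned(self, centred_pair):
        cfg, mother, daughter = centred_pair
        vol = render_pair(cfg, mother, daughter)
        pair = spa.fit_spb_pair(vol, np.stack([mother, daughter]))
        out = spa.realign(vol, pair)
        # already on-axis and centred: realignment is a (near-)identity
        assert np.abs(out.volume.voxels - vol.voxels).max() < 0.02 * vol.voxels.max()

    def test_rotated_pair_realigned_to_x_axis(self, centred_pair):
        cfg, _, _ = centred_pair
        from npcquant.simulate import _grid_geometry
        _, center = _grid_geometry(cfg)
        axis = np.array([math.cos(1.2), math.sin(1.2), 0.0])
        mother = center - 90.0 * axis
        daughter = center + 90.0 * axis
        vol = render_pair(cfg, mother, daughter)
        pair = spa.fit_spb_pair(vol, np.stack([mother + 20, daughter - 20]))
        aligned = spa.realign(vol, pair)
        # refit on the realigned volume: axis within 1 degree of +x
        nz, ny, nx = aligned.volume.shape
        cx = nx * cfg.pixel_nm / 2.0
        cy = ny * cfg.pixel_nm / 2.0
        seeds = np.array([[cx - 90.0, cy, pair.midpoint_nm[2]],
                          [cx + 90.0, cy, pair.midpoint_nm[2]]])
        refit = spa.fit_spb_pair(aligned.volume, seeds)
        d = refit.daughter_nm - refit.mother_nm
        angle = math.degrees(math.atan2(d[1], d[0]))
        assert abs(angle) < 1.0
        assert refit.separation_nm == pytest.approx(pair.separation_nm, abs=1.0)
        assert refit.mother_nm[0] < refit.daughter_nm[0]  # mother on -x side

    def test_zero_separation_rejected(self, centred_pair):
        cfg, mother, _ = centred_pair
        vol = render_pair(cfg, mother, mother + np.array([0, 0, 1.0]))
        pair = spa.SPBPair(mother, mother + np.array([0, 0, 1.0]),
                           1.0, 0.5, 40.0, 120.0, 0.0)
        with pytest.raises(ValueError):
            spa.realign(vol, pair)


class TestAveraging:
    def _aligned_from(self, vox, mid_z=250.0):
        vol = VolumeImage(vox, 40.0, 125.0)
        return spa.AlignedVolume(vol, 0.0, np.zeros(2), mid_z, 180.0)

    def test_single_input_mean_is_projection(self):
        rng = np.random.default_rng(0)
        vox = rng.uniform(1, 2, size=(4, 64, 64))
        av = self._aligned_from(vox)
        out = spa.average_maps([av], mirror=False, z_halfwidth_nm=None,
                               crop_half_nm=1280.0)
        np.testing.assert_allclose(out.image, vox.sum(axis=0))

    def test_mirrored_map_symmetric(self):
        rng = np.random.default_rng(1)
        vox = rng.uniform(0, 5, size=(4, 64, 64))
        out = spa.average_maps([self._aligned_from(vox)], mirror=True)
        np.testing.assert_allclose(out.image, out.image[::-1, :], atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            spa.average_maps([])

    def test_display_threshold_only_affects_rendering(self):
        vox = np.zeros((2, 64, 64))
        vox[0, 32, 32] = 100.0
        vox[0, 10, 10] = 10.0
        out = spa.average_maps([self._aligned_from(vox, mid_z=62.5)],
                               mirror=False, z_halfwidth_nm=None)
        disp = out.display_image()
        assert disp.max() == out.image.max()
        assert (disp > 0).sum() < (out.image > 0).sum()

    def test_scale_commutes_through_chain(self):
        rng = np.random.default_rng(2)
        vox = rng.uniform(1, 3, size=(4, 64, 64))
        a1 = self._aligned_from(vox)
        a2 = self._aligned_from(7.0 * vox)
        m1 = spa.average_maps([a1], mirror=True, z_halfwidth_nm=None)
        m2 = spa.average_maps([a2], mirror=True, z_halfwidth_nm=None)
        np.testing.assert_allclose(m2.image, 7.0 * m1.image, rtol=1e-12)
        p1 = spa.axis_profile(m1)
        p2 = spa.axis_profile(m2)
        np.testing.assert_allclose(p1.intensities, p2.intensities, rtol=1e-12)


class TestAxisProfile:
    def test_uniform_map_flat_profile(self):
        m = spa.AverageMap(np.ones((50, 50)), n=1, mirrored=False, pixel_nm=40.0)
        prof = spa.axis_profile(m)
        np.testing.assert_allclose(prof.intensities, 1.0)

    def test_width_exceeding_map_rejected(self):
        m = spa.AverageMap(np.ones((8, 50)), n=1, mirrored=False, pixel_nm=40.0)
        with pytest.raises(ValueError):
            spa.axis_profile(m, width_px=12)


class TestExclusionCall:
    def test_flat_profile_not_excluded(self):
        prof = spa.Profile(np.arange(-500.0, 501.0, 40.0),
                           np.ones(26), width_px=12)
        res = spa.exclusion_fwhm(prof)
        assert not res.excluded and res.fit is None

    def test_synthetic_dip_sd85_gives_fwhm_200(self):
        # closed form: 2.355 x 85 = 200.2 nm
        x = np.arange(-500.0, 501.0, 40.0)
        y = 1.0 - 0.6 * np.exp(-0.5 * (x / 85.0) ** 2)
        res = spa.exclusion_fwhm(spa.Profile(x, y, 12))
        assert res.excluded and res.fit.converged
        assert res.fit.fwhm_nm == pytest.approx(200.2, abs=2.0)
        assert res.fit.fwhm_nm / res.fit.sd_nm == FWHM_FACTOR

    def test_ci_brackets_fwhm(self):
        rng = np.random.default_rng(3)
        x = np.arange(-500.0, 501.0, 40.0)
        y = 1.0 - 0.5 * np.exp(-0.5 * (x / 100.0) ** 2) + rng.normal(0, 0.02, x.size)
        res = spa.exclusion_fwhm(spa.Profile(x, y, 12))
        lo, hi = res.fit.fwhm_ci95_nm
        assert lo < res.fit.fwhm_nm < hi


class TestProximalDistal:
    def _pair(self):
        return spa.SPBPair(np.array([-90.0, 0, 0]), np.array([90.0, 0, 0]),
                           1.0, 0.7, 40.0, 120.0, 0.0)

    def test_type_one_error_calibrated(self):
        # identical intensity distributions: rejection rate ~ alpha
        rng = np.random.default_rng(4)
        pair = self._pair()
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            coords = np.vstack([
                rng.normal(scale=50.0, size=(30, 3)),           # proximal
                rng.normal(scale=50.0, size=(30, 3)) + 2000.0,  # distal
            ])
            foci = FociSet(coords, rng.lognormal(0.0, 0.3, 60))
            res = spa.proximal_distal(foci, pair)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_power_against_50pct_reduction(self):
        rng = np.random.default_rng(5)
        pair = self._pair()
        coords = np.vstack([rng.normal(scale=50.0, size=(30, 3)),
                            rng.normal(scale=50.0, size=(30, 3)) + 2000.0])
        inten = np.concatenate([rng.lognormal(0, 0.3, 30) * 0.5,
                                rng.lognormal(0, 0.3, 30)])
        res = spa.proximal_distal(FociSet(coords, inten), pair)
        assert res.p_value < 0.01
        assert res.mean_proximal < res.mean_distal

    def test_all_distal_flagged_missing(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(scale=50.0, size=(20, 3)) + 3000.0
        res = spa.proximal_distal(FociSet(coords, np.ones(20)), self._pair())
        assert res.p_value is None and res.mean_proximal is None
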