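"""End-to-end simulation studies: the package run on its own synthetic data.

These are the reusable drivers behind the ``analysis/`` scripts, the
acceptance recomputation and the heavier tests: density-recovery calibration
across a radius x density grid, the random-NPC SPA null (and its constructed
exclusion-zone counterpart), SPB-pair separation recovery, and nucleolar
reduction recovery. Every study takes a master seed and derives per-image
child seeds from it, so results are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import spa
from .detect import DetectionParams, detect_foci
from .hull import fit_hull
from .quantify import summarize_nucleus
from .segment import SegmentationParams, segment_nuclei
from .simulate import (FociTruth, SimConfig, apply_camera,
                       generate_condition_grid, render_volume,
                       sample_points_on_sphere, sample_spb_pair)
from .volume import VolumeImage


def measure_nucleus(volume: VolumeImage,
                    seg_params: SegmentationParams | None = None,
                    det_params: DetectionParams | None = None):
    """Segmentation -> detection -> hull -> per-nucleus record, largest nucleus.

    Returns ``(mask, foci, hull_result, record)``; ``(None, ...)`` when no
    nucleus is found.
    """
    masks = segment_nuclei(volume.max_projection(), volume.pixel_nm, seg_params)
    if not masks:
        return None, None, None, None
    mask = max(masks, key=lambda m: m.area_px)
    foci = detect_foci(volume, mask, det_params)
    if foci.n < 4:
        return mask, foci, None, None
    hull = fit_hull(foci.coordinates_nm)
    return mask, foci, hull, summarize_nucleus(foci, hull)


def density_calibration(radii_nm=(1000.0, 1250.0, 1500.0),
                        densities=(4.0, 5.0, 6.0, 7.0),
                        n_per_condition: int = 20,
                        seed: int = 0) -> pd.DataFrame:
    """Recover NPC density from simulated nuclei across a radius x density grid.

    For each image: simulate (default PSF/camera), run the full measurement
    chain, and record measured count / surface area / density against the
    truth. The percent error of measured density is the headline column.
    """
    manifest = generate_condition_grid(radii_nm, densities, n_per_condition, seed)
    rows = []
    for rec in manifest.itertuples(index=False):
        config = SimConfig(radius_nm=rec.radius_nm, n_npcs=rec.n_npcs,
                           seed=int(rec.seed))
        rng = config.rng()
        truth = sample_points_on_sphere(config, rng)
        vol = apply_camera(render_volume(truth, config), config, rng)
        _, foci, hull, record = measure_nucleus(vol)
        if record is None:
            continue
        rows.append({
            "image_id": rec.image_id,
            "radius_nm": rec.radius_nm,
            "true_density_per_um2": rec.true_density_per_um2,
            "true_n": rec.n_npcs,
            "true_sa_um2": rec.true_sa_um2,
            "measured_n": record.npc_count,
            "measured_sa_um2": record.surface_area_um2,
            "measured_density_per_um2": record.density_per_um2,
            "density_pct_error": 100.0 * (record.density_per_um2
                                          - rec.true_density_per_um2)
                                 / rec.true_density_per_um2,
        })
    return pd.DataFrame(rows)


@dataclass
class SPAStudyResult:
    """Output of a simulated SPA run (null or constructed exclusion zone)."""

    avg_map: spa.AverageMap
    profile: spa.Profile
    value_at_spb: float           # min of the profile at the two SPB positions
    n_aligned: int
    n_failed: int
    exclusion: spa.ExclusionResult
    separations_nm: np.ndarray    # fitted pair separations of contributing nuclei


def spa_study(n_nuclei: int = 100, seed: int = 0,
              exclusion_radius_nm: float | None = None,
              config: SimConfig | None = None,
              seed_jitter_nm: float = 30.0,
              mirror: bool = True) -> SPAStudyResult:
    """Full SPA chain on simulated nuclei with SPB landmark pairs.

    Per nucleus: sample the SPB pair, sample NPCs (uniform, or with a
    forbidden zone of ``exclusion_radius_nm`` around the SPB midpoint for the
    constructed-exclusion study), render both channels with the camera model,
    segment the NPC channel, fit the SPB pair from jittered truth seeds,
    apply the 400 nm edge filter, realign the NPC channel, then average
    (with mirroring), extract the 12-pixel axis profile and evaluate it at
    the true SPB positions (+- half the pair separation).
    """
    base = config or SimConfig(n_npcs=125, seed=None)
    child = np.random.SeedSequence(seed).generate_state(n_nuclei) % (2**31)
    aligned = []
    seps = []
    n_failed = 0
    half_sep = base.spb_separation_nm / 2.0
    for s in child:
        cfg = replace(base, seed=int(s))
        rng = cfg.rng()
        try:
            spb_truth = sample_spb_pair(cfg, rng)
            truth = sample_points_on_sphere(
                cfg, rng,
                forbidden_centers_nm=spb_truth.midpoint_nm[None, :]
                if exclusion_radius_nm else None,
                forbidden_radius_nm=exclusion_radius_nm or 0.0)
            npc_vol = apply_camera(render_volume(truth, cfg), cfg, rng)
            spb_pts = np.stack([spb_truth.mother_nm, spb_truth.daughter_nm])
            spb_render = render_volume(FociTruth(
                positions_nm=spb_pts,
                intensities=np.array([spb_truth.mother_intensity,
                                      spb_truth.daughter_intensity]),
                sphere_center_nm=truth.sphere_center_nm,
                radius_nm=truth.radius_nm), cfg)
            spb_vol = apply_camera(spb_render, cfg, rng)
            seeds = spb_pts + rng.normal(0.0, seed_jitter_nm, spb_pts.shape)
            pair = spa.fit_spb_pair(spb_vol, seeds)
            masks = segment_nuclei(npc_vol.max_projection(), npc_vol.pixel_nm)
            if not masks:
                n_failed += 1
                continue
            mask = max(masks, key=lambda m: m.area_px)
            if not spa.edge_filter(pair, mask, npc_vol.pixel_nm):
                n_failed += 1
                continue
            aligned.append(spa.realign(npc_vol, pair))
            seps.append(pair.separation_nm)
        except (spa.SPBFitError, ValueError):
            n_failed += 1
    if not aligned:
        raise RuntimeError("no nuclei survived the SPA chain")
    avg = spa.average_maps(aligned, mirror=mirror)
    profile = spa.axis_profile(avg)
    value = min(profile.value_at(-half_sep), profile.value_at(half_sep))
    return SPAStudyResult(
        avg_map=avg, profile=profile, value_at_spb=value,
        n_aligned=len(aligned), n_failed=n_failed,
        exclusion=spa.exclusion_fwhm(profile),
        separations_nm=np.asarray(seps),
    )


def spb_separation_recovery(n_replicates: int = 50, seed: int = 0,
                            config: SimConfig | None = None,
                            seed_jitter_nm: float = 30.0) -> np.ndarray:
    """Fitted pair separations from simulated SPB channels (one per replicate)."""
    base = config or SimConfig(n_npcs=125, seed=None)
    child = np.random.SeedSequence([seed, 1]).generate_state(n_replicates) % (2**31)
    seps = []
    for s in child:
        cfg = replace(base, seed=int(s))
        rng = cfg.rng()
        spb_truth = sample_spb_pair(cfg, rng)
        pts = np.stack([spb_truth.mother_nm, spb_truth.daughter_nm])
        vol = apply_camera(render_volume(FociTruth(
            positions_nm=pts,
            intensities=np.array([spb_truth.mother_intensity,
                                  spb_truth.daughter_intensity]),
            sphere_center_nm=np.zeros(3), radius_nm=cfg.radius_nm), cfg), cfg, rng)
        seeds = pts + rng.normal(0.0, seed_jitter_nm, pts.shape)
        pair = spa.fit_spb_pair(vol, seeds)
        seps.append(pair.separation_nm)
    return np.asarray(seps)


def nucleolar_recovery(reduction: float, n_scenes: int = 50,
                       noise_sd: float = 0.1, seed: int = 0) -> dict:
    """Recover a constructed nucleolar Nup reduction from noisy scenes.

    Returns the mean / SD / SE of the normalised Nup value at position 0
    across ``n_scenes`` independently rotated scenes (truth: 1 - reduction).
    """
    from .nucleolar import NEProfilePair, align_and_average, nup_reduction_at_center
    from .simulate import generate_nucleolar_scene
    child = np.random.SeedSequence([seed, 2]).generate_state(n_scenes) % (2**31)
    pairs = []
    for i, s in enumerate(child):
        scene = generate_nucleolar_scene(nup_reduction_frac=reduction,
                                         noise_sd=noise_sd, seed=int(s))
        pairs.append(NEProfilePair(positions_nm=scene.positions_nm,
                                   nup=scene.nup, marker=scene.marker,
                                   nucleus_id=f"scene{i:03d}"))
    aligned = align_and_average(pairs)
    mean, sd = nup_reduction_at_center(aligned)
    return {"mean": mean, "sd": sd, "se": sd / np.sqrt(aligned.n),
            "n": aligned.n, "truth": 1.0 - reduction}
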