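"""Independent oracles used by the test suite.

Each oracle recomputes an expected result by a route disjoint from the
implementation it checks: brute-force enumeration, closed forms, or a direct
continuum computation of the expected image statistic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import replace

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.special import erf

from npcquant.simulate import SimConfig, sample_points_on_sphere, sample_spb_pair
from npcquant.spa import Profile


def brute_force_pairwise_min(points: np.ndarray) -> float:
    """Minimum pairwise distance via the full distance matrix."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    return float(d[np.triu_indices(len(points), k=1)].min())


def brute_force_codetect_fraction(a: np.ndarray, b: np.ndarray, radius: float) -> float:
    """Fraction of rows of `a` with any row of `b` within `radius` (O(n^2))."""
    hits = 0
    for p in a:
        if np.any(np.sqrt(((b - p) ** 2).sum(1)) <= radius):
            hits += 1
    return hits / len(a)


def on_hull_fraction(points: np.ndarray, eps_nm: float = 20.0) -> float:
    hull = ConvexHull(points)
    d = points @ hull.equations[:, :3].T + hull.equations[:, 3]
    on = d.max(axis=1) >= -eps_nm
    on[hull.vertices] = True
    return on.mean()


def exhaustive_best_fraction(points: np.ndarray, max_removal_frac: float = 0.10,
                             eps_nm: float = 20.0) -> float:
    """Best on-hull fraction over ALL removal subsets up to the cap."""
    n = len(points)
    cap = int(math.floor(max_removal_frac * n))
    best = on_hull_fraction(points, eps_nm)
    idx = np.arange(n)
    for k in range(1, cap + 1):
        for subset in itertools.combinations(range(n), k):
            keep = np.setdiff1d(idx, subset)
            if len(keep) < 4:
                continue
            try:
                f = on_hull_fraction(points[keep], eps_nm)
            except QhullError:
                continue
            best = max(best, f)
    return best


def expected_spa_band_profile(n_nuclei: int, seed: int,
                              exclusion_radius_nm: float | None = None,
                              width_px: int = 12, halfwidth_nm: float = 500.0,
                              z_halfwidth_nm: float = 375.0,
                              smooth_px: int = 3,
                              config: SimConfig | None = None) -> Profile:
    """Continuum computation of the averaged SPA band profile.

    Uses the same ground-truth point process (identical seed stream as
    ``experiments.spa_study``) but skips every imaging step: no raster, no
    camera noise, no segmentation, no fitting, no interpolation. Each emitter
    contributes its anisotropic-Gaussian intensity analytically — the x term
    at the profile sample positions, the y term integrated over the 12-pixel
    band, the z term summed over the slices inside the axial window — in the
    frame aligned on the *true* SPB pair. Any agreement with the pipeline's
    profile therefore validates the rendering/detection/fit/realign chain.
    """
    base = config or SimConfig(n_npcs=125, seed=None)
    child = np.random.SeedSequence(seed).generate_state(n_nuclei) % (2**31)
    px = base.pixel_nm
    sxy = base.sigma_xy_nm
    sz = base.sigma_z_nm
    # same sample positions as the pipeline's axis_profile (40 nm steps, +-500)
    xs = np.arange(-halfwidth_nm, halfwidth_nm + px / 2.0, px)
    W = width_px * px
    y0, y1 = -W / 2.0, W / 2.0
    acc = np.zeros_like(xs)
    for s in child:
        cfg = replace(base, seed=int(s))
        rng = cfg.rng()
        st = sample_spb_pair(cfg, rng)
        tr = sample_points_on_sphere(
            cfg, rng,
            forbidden_centers_nm=st.midpoint_nm[None, :] if exclusion_radius_nm else None,
            forbidden_radius_nm=exclusion_radius_nm or 0.0)
        mid = st.midpoint_nm
        d = st.daughter_nm - st.mother_nm
        alpha = math.atan2(d[1], d[0])
        rel = tr.positions_nm - mid
        xr = math.cos(alpha) * rel[:, 0] + math.sin(alpha) * rel[:, 1]
        yr = -math.sin(alpha) * rel[:, 0] + math.cos(alpha) * rel[:, 1]
        zc = (np.arange(int(tr.positions_nm[:, 2].max() / base.zstep_nm) + 10) + 0.5) \
            * base.zstep_nm
        zsel = zc[np.abs(zc - mid[2]) <= z_halfwidth_nm]
        wz = np.exp(-0.5 * ((zsel[None, :] - tr.positions_nm[:, 2][:, None]) / sz) ** 2).sum(1)
        wy = (np.sqrt(2 * np.pi) * sxy / W) * 0.5 * (
            erf((y1 - yr) / (np.sqrt(2) * sxy)) - erf((y0 - yr) / (np.sqrt(2) * sxy)))
        gx = np.exp(-0.5 * ((xs[None, :] - xr[:, None]) / sxy) ** 2)
        acc += (gx * (wz * wy)[:, None]).sum(0)
    prof = acc / n_nuclei
    if smooth_px > 1:
        kernel = np.ones(smooth_px) / smooth_px
        prof = np.convolve(np.pad(prof, smooth_px, mode="edge"), kernel,
                           mode="same")[smooth_px:-smooth_px]
    return Profile(positions_nm=xs, intensities=prof / prof.mean(), width_px=width_px)
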