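"""Single-particle averaging (SPA) around the SPB landmark pair.

Many nuclei are brought into a common frame defined by the two spindle-pole
bodies: the pair is fitted jointly as two 3D Gaussians, nuclei whose SPBs sit
too close to the projected nuclear rim are discarded (the 400 nm edge filter
keeps only top-down views, where the NE around the SPB is a roughly flat cap),
each volume is rotated in-plane so the mother-daughter axis lies along +x with
the midpoint at the frame centre, and the realigned views are averaged —
optionally together with their x-axis mirror image, since left/right bias in
the dataset is biologically meaningless.

NPC exclusion is then read off the averaged map: a 12-pixel-wide line profile
along the SPB axis, normalised to its maximum; a protein is called excluded
when the profile drops below 0.8 (the threshold anchored to simulations of
randomly distributed NPCs, which stay above it), and the zone width is the
FWHM (= 2.355 x SD) of an inverted-Gaussian fit to the dip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.stats import mannwhitneyu

from .detect import FociSet
from .gaussian import FWHM_FACTOR, GaussianFit, fit_gaussian_1d
from .segment import NucleusMask
from .volume import VolumeImage


class SPBFitError(RuntimeError):
    """Raised when the two-Gaussian SPB fit cannot be trusted."""


@dataclass
class SPBPair:
    """Jointly fitted mother/daughter landmark centers (mother = brighter)."""

    mother_nm: np.ndarray
    daughter_nm: np.ndarray
    mother_amplitude: float
    daughter_amplitude: float
    sigma_xy_nm: float
    sigma_z_nm: float
    baseline: float

    @property
    def separation_nm(self) -> float:
        return float(np.linalg.norm(self.mother_nm - self.daughter_nm))

    @property
    def midpoint_nm(self) -> np.ndarray:
        return 0.5 * (self.mother_nm + self.daughter_nm)

    @property
    def daughter_mother_ratio(self) -> float:
        return self.daughter_amplitude / self.mother_amplitude


def fit_spb_pair(volume: VolumeImage, approx_centers_nm: np.ndarray,
                 crop_half_xy_nm: float = 500.0,
                 crop_half_z_nm: float = 600.0) -> SPBPair:
    """Joint least-squares fit of two 3D Gaussians + shared baseline.

    ``approx_centers_nm`` is a (2, 3) array of seed positions (manual clicks,
    or simulator truth jittered). The fit shares one lateral and one axial SD
    between the two spots. Fails (raises :class:`SPBFitError`) on
    non-convergence, on centers that swap across the seeds, or on a collapsed
    pair (separation < 20 nm), e.g. when both seeds land on a single spot.
    """
    seeds = np.asarray(approx_centers_nm, dtype=float)
    if seeds.shape != (2, 3):
        raise ValueError("approx_centers_nm must be (2, 3)")
    lo = seeds.min(axis=0) - np.array([crop_half_xy_nm, crop_half_xy_nm, crop_half_z_nm])
    hi = seeds.max(axis=0) + np.array([crop_half_xy_nm, crop_half_xy_nm, crop_half_z_nm])
    nz, ny, nx = volume.shape
    x0 = max(int(lo[0] / volume.pixel_nm), 0)
    y0 = max(int(lo[1] / volume.pixel_nm), 0)
    z0 = max(int(lo[2] / volume.zstep_nm), 0)
    x1 = min(int(math.ceil(hi[0] / volume.pixel_nm)), nx)
    y1 = min(int(math.ceil(hi[1] / volume.pixel_nm)), ny)
    z1 = min(int(math.ceil(hi[2] / volume.zstep_nm)), nz)
    if x1 - x0 < 3 or y1 - y0 < 3 or z1 - z0 < 3:
        raise SPBFitError("crop around the seeds is too small to fit")
    data = volume.voxels[z0:z1, y0:y1, x0:x1]
    xc = (np.arange(x0, x1) + 0.5) * volume.pixel_nm
    yc = (np.arange(y0, y1) + 0.5) * volume.pixel_nm
    zc = (np.arange(z0, z1) + 0.5) * volume.zstep_nm
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")

    base0 = float(np.median(data))
    amp0 = max(float(data.max()) - base0, 1.0)

    def model(p):
        a1, a2 = p[0], p[1]
        c1, c2 = p[2:5], p[5:8]
        sxy, sz, base = p[8], p[9], p[10]
        g1 = a1 * np.exp(-0.5 * (((X - c1[0]) / sxy) ** 2 + ((Y - c1[1]) / sxy) ** 2
                                 + ((Z - c1[2]) / sz) ** 2))
        g2 = a2 * np.exp(-0.5 * (((X - c2[0]) / sxy) ** 2 + ((Y - c2[1]) / sxy) ** 2
                                 + ((Z - c2[2]) / sz) ** 2))
        return g1 + g2 + base

    p0 = np.array([amp0, amp0, *seeds[0], *seeds[1], 45.0, 130.0, base0])
    lower = np.concatenate([[0.0, 0.0], lo, lo, [5.0, 5.0, -np.inf]])
    upper = np.concatenate([[np.inf, np.inf], hi, hi, [1000.0, 2000.0, np.inf]])
    res = least_squares(lambda p: (model(p) - data).ravel(), p0,
                        bounds=(lower, upper), max_nfev=400)
    if not res.success and res.status <= 0:
        raise SPBFitError(f"SPB fit did not converge: {res.message}")
    p = res.x
    c1, c2 = p[2:5].copy(), p[5:8].copy()
    sep = float(np.linalg.norm(c1 - c2))
    if sep < 20.0:
        raise SPBFitError(f"fitted spots collapsed (separation {sep:.1f} nm)")
    # Swap check: each center must stay nearer its own seed.
    if (np.linalg.norm(c1 - seeds[0]) > np.linalg.norm(c1 - seeds[1])
            or np.linalg.norm(c2 - seeds[1]) > np.linalg.norm(c2 - seeds[0])):
        raise SPBFitError("fitted centers crossed their seeds")
    a1, a2 = float(p[0]), float(p[1])
    if a1 >= a2:
        mother, daughter, am, ad = c1, c2, a1, a2
    else:
        mother, daughter, am, ad = c2, c1, a2, a1
    return SPBPair(mother_nm=mother, daughter_nm=daughter,
                   mother_amplitude=am, daughter_amplitude=ad,
                   sigma_xy_nm=float(p[8]), sigma_z_nm=float(p[9]),
                   baseline=float(p[10]))


def edge_filter(pair: SPBPair, mask: NucleusMask, pixel_nm: float,
                min_nm: float = 400.0) -> bool:
    """True iff both projected SPB centers are >= ``min_nm`` inside the mask.

    Distances are Euclidean distances to the mask boundary in the maximum-
    intensity-projection frame; a center outside the mask fails (distance 0).
    """
    dist_px = ndimage.distance_transform_edt(mask.mask)
    for c in (pair.mother_nm, pair.daughter_nm):
        col = int(c[0] / pixel_nm)
        row = int(c[1] / pixel_nm)
        if not (0 <= row < mask.mask.shape[0] and 0 <= col < mask.mask.shape[1]):
            return False
        if dist_px[row, col] * pixel_nm < min_nm:
            return False
    return True


@dataclass
class AlignedVolume:
    """A volume resampled into the SPB frame (pair along +x, midpoint centred)."""

    volume: VolumeImage
    rotation_deg: float
    translation_nm: np.ndarray     # lateral shift applied (x, y)
    spb_mid_z_nm: float
    separation_nm: float


def realign(volume: VolumeImage, pair: SPBPair) -> AlignedVolume:
    """In-plane rigid realignment onto the SPB axis.

    Rotates about z so the mother->daughter axis lies along +x (mother on the
    -x side) and translates the pair midpoint to the lateral frame centre;
    z is untouched. Bilinear lateral interpolation.
    """
    delta = pair.daughter_nm - pair.mother_nm
    if np.hypot(delta[0], delta[1]) < 1e-9:
        raise ValueError("zero lateral separation; axis undefined")
    alpha = math.atan2(delta[1], delta[0])
    nz, ny, nx = volume.shape
    cx = nx * volume.pixel_nm / 2.0
    cy = ny * volume.pixel_nm / 2.0
    mid = pair.midpoint_nm
    cos_a, sin_a = math.cos(alpha), math.sin(alpha)
    xo = (np.arange(nx) + 0.5) * volume.pixel_nm - cx
    yo = (np.arange(ny) + 0.5) * volume.pixel_nm - cy
    XO, YO = np.meshgrid(xo, yo)
    # output frame point -> input point: rotate +x onto the pair axis, then
    # shift to the midpoint.
    xi = cos_a * XO - sin_a * YO + mid[0]
    yi = sin_a * XO + cos_a * YO + mid[1]
    col = xi / volume.pixel_nm - 0.5
    row = yi / volume.pixel_nm - 0.5
    out = np.empty_like(volume.voxels)
    for iz in range(nz):
        out[iz] = ndimage.map_coordinates(volume.voxels[iz], [row, col],
                                          order=1, mode="constant", cval=0.0)
    aligned = VolumeImage(out, pixel_nm=volume.pixel_nm, zstep_nm=volume.zstep_nm,
                          channel=volume.channel)
    return AlignedVolume(
        volume=aligned,
        rotation_deg=math.degrees(-alpha),
        translation_nm=np.array([cx - mid[0], cy - mid[1]]),
        spb_mid_z_nm=float(mid[2]),
        separation_nm=pair.separation_nm,
    )


@dataclass
class AverageMap:
    """Mean projected image in the SPB frame."""

    image: np.ndarray
    n: int
    mirrored: bool
    pixel_nm: float
    display_threshold: float = 0.25

    def display_image(self) -> np.ndarray:
        """Rendering view only: pixels below 25% of the max are clipped."""
        cut = self.display_threshold * self.image.max()
        return np.where(self.image >= cut, self.image, 0.0)


def _cap_projection(av: AlignedVolume, z_halfwidth_nm: float | None) -> np.ndarray:
    vox = av.volume.voxels
    if z_halfwidth_nm is None:
        return vox.sum(axis=0)
    zc = (np.arange(vox.shape[0]) + 0.5) * av.volume.zstep_nm
    sel = np.abs(zc - av.spb_mid_z_nm) <= z_halfwidth_nm
    if not sel.any():
        sel[np.argmin(np.abs(zc - av.spb_mid_z_nm))] = True
    return vox[sel].sum(axis=0)


def average_maps(aligned: list[AlignedVolume], mirror: bool = True,
                 z_halfwidth_nm: float | None = 375.0,
                 crop_half_nm: float = 1000.0) -> AverageMap:
    """Average the realigned views into one map.

    Each volume is sum-projected over an axial window (default +-375 nm)
    around its fitted SPB mid-plane — the top-down cap view — cropped to a
    central box around the SPB frame centre, and averaged voxelwise. With
    ``mirror`` the mean is further averaged with its x-axis flip, enforcing
    up/down symmetry. ``z_halfwidth_nm=None`` sum-projects the whole stack.
    """
    if not aligned:
        raise ValueError("no aligned volumes to average")
    px = aligned[0].volume.pixel_nm
    half_px = int(round(crop_half_nm / px))
    acc = None
    for av in aligned:
        if av.volume.shape[1:] != aligned[0].volume.shape[1:]:
            raise ValueError("aligned volumes must share lateral dimensions")
        proj = _cap_projection(av, z_halfwidth_nm)
        ny, nx = proj.shape
        r0 = max(ny // 2 - half_px, 0)
        c0 = max(nx // 2 - half_px, 0)
        crop = proj[r0:ny // 2 + half_px, c0:nx // 2 + half_px]
        acc = crop.astype(float) if acc is None else acc + crop
    mean = acc / len(aligned)
    if mirror:
        mean = 0.5 * (mean + mean[::-1, :])
    return AverageMap(image=mean, n=len(aligned), mirrored=mirror, pixel_nm=px)


@dataclass
class Profile:
    """A normalised line profile along the SPB axis (positions in nm, centred)."""

    positions_nm: np.ndarray
    intensities: np.ndarray
    width_px: int

    def value_at(self, x_nm: float) -> float:
        return float(np.interp(x_nm, self.positions_nm, self.intensities))


def axis_profile(avg: AverageMap, width_px: int = 12,
                 halfwidth_nm: float = 500.0, smooth_px: int = 3) -> Profile:
    """Band-averaged profile along +x through the frame centre.

    Averages a ``width_px``-pixel-wide band in y, restricts to
    ``+- halfwidth_nm`` in x, lightly boxcar-smooths (``smooth_px``) and
    normalises to the profile *mean* — the local NE level, which anchors the
    0.8 exclusion call. A single-point maximum would be a biased reference:
    with a handful of pores contributing per 40 nm column even a many-nucleus
    average retains ~10% sampling noise, and dividing by its highest
    excursion would drag a perfectly random profile below the exclusion
    threshold.
    """
    img = avg.image
    ny, nx = img.shape
    if width_px > ny:
        raise ValueError(f"band width {width_px} px exceeds map height {ny}")
    r0 = ny // 2 - width_px // 2
    band = img[r0:r0 + width_px, :].mean(axis=0)
    x = (np.arange(nx) + 0.5 - nx / 2.0) * avg.pixel_nm
    sel = np.abs(x) <= halfwidth_nm
    band, x = band[sel], x[sel]
    if smooth_px > 1:
        kernel = np.ones(smooth_px) / smooth_px
        pad = smooth_px
        band = np.convolve(np.pad(band, pad, mode="edge"), kernel,
                           mode="same")[pad:-pad]
    ref = band.mean()
    if ref <= 0:
        raise ValueError("profile has no signal to normalise")
    return Profile(positions_nm=x, intensities=band / ref, width_px=width_px)


@dataclass
class ExclusionResult:
    excluded: bool
    fit: GaussianFit | None
    min_intensity: float


def exclusion_fwhm(profile: Profile, threshold: float = 0.8,
                   fit_window_nm: float = 1000.0,
                   flank_frac: float = 0.25) -> ExclusionResult:
    """Call exclusion (min < threshold) and size the zone by an inverted fit.

    The dip is fitted as ``baseline - amp * Gaussian`` over the central
    ``fit_window_nm``, with the baseline pinned to the mean of the outer
    flanks (the outer ``flank_frac`` of the window on each side) — leaving it
    free lets the fit chase the deepest few points with an unrealistically
    narrow Gaussian. FWHM = 2.355 x SD with the 95% CI from the covariance.
    A non-convergent fit is returned flagged, with no FWHM.
    """
    from scipy.optimize import curve_fit

    mn = float(profile.intensities.min())
    if mn >= threshold:
        return ExclusionResult(excluded=False, fit=None, min_intensity=mn)
    sel = np.abs(profile.positions_nm) <= fit_window_nm / 2.0
    x = profile.positions_nm[sel]
    y = profile.intensities[sel]
    n_flank = max(int(round(flank_frac * len(x) / 2.0)), 2)
    baseline = float(np.mean(np.concatenate([y[:n_flank], y[-n_flank:]])))

    def dip(xv, amp, center, sd):
        return baseline - amp * np.exp(-0.5 * ((xv - center) / sd) ** 2)

    try:
        popt, pcov = curve_fit(
            dip, x, y, p0=[baseline - mn, x[int(np.argmin(y))], 100.0],
            bounds=([0.0, x.min(), 10.0], [np.inf, x.max(), np.ptp(x)]),
            maxfev=20000)
        amp, center, sd = popt
        se_sd = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.nan
        fit = GaussianFit(amplitude=float(amp), center_nm=float(center),
                          sd_nm=float(sd), baseline=baseline, se_sd_nm=se_sd,
                          converged=True, inverted=True)
    except (RuntimeError, ValueError):
        fit = GaussianFit(0.0, 0.0, np.nan, baseline, np.nan,
                          converged=False, inverted=True)
    return ExclusionResult(excluded=True, fit=fit, min_intensity=mn)


@dataclass
class ProximalDistalResult:
    proximal_intensities: np.ndarray
    distal_intensities: np.ndarray
    statistic: float | None
    p_value: float | None
    mean_proximal: float | None
    mean_distal: float | None


def proximal_distal(foci: FociSet, pair: SPBPair,
                    radius_nm: float = 100.0) -> ProximalDistalResult:
    """Compare focus intensities proximal vs distal to the SPBs.

    Foci are partitioned by the minimum distance to either fitted SPB centre
    (proximal: within ``radius_nm``); intensities are normalised by the
    overall mean and compared with a two-sided Wilcoxon rank-sum test
    (normal approximation with tie correction). An empty group yields
    missing statistics rather than an error.
    """
    if foci.n == 0:
        return ProximalDistalResult(np.empty(0), np.empty(0), None, None, None, None)
    d_m = np.linalg.norm(foci.coordinates_nm - pair.mother_nm, axis=1)
    d_d = np.linalg.norm(foci.coordinates_nm - pair.daughter_nm, axis=1)
    prox_sel = np.minimum(d_m, d_d) <= radius_nm
    norm = foci.intensities / foci.intensities.mean()
    prox = norm[prox_sel]
    dist = norm[~prox_sel]
    if prox.size == 0 or dist.size == 0:
        return ProximalDistalResult(
            prox, dist, None, None,
            float(prox.mean()) if prox.size else None,
            float(dist.mean()) if dist.size else None,
        )
    stat, p = mannwhitneyu(prox, dist, alternative="two-sided", method="asymptotic")
    return ProximalDistalResult(prox, dist, float(stat), float(p),
                                float(prox.mean()), float(dist.mean()))
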