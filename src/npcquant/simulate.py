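"""Synthetic nuclei rendered as noisy 3D-SIM-like volumes.

Ground truth is a spherical nuclear envelope decorated with NPCs: points
placed uniformly at random on the sphere subject to a minimum center-to-center
spacing (a hard-core process, since two pores cannot overlap). Each pore is
rendered as an anisotropic 3D Gaussian — FWHM 100 nm laterally and 300 nm
axially by default, the effective 3D-SIM point-spread function — at 100 peak
photons, then passed through a camera model: optional Poisson shot noise, a
multiplicative gain of 20, and additive Gaussian read noise (SD 40 intensity
units). Default sampling is 40 nm pixels with 125 nm z-steps.

A second channel can carry a spindle-pole-body (SPB) landmark pair, two spots
180 nm apart placed in the top polar cap so the downstream top-down
single-particle-averaging geometry (and its 400 nm edge filter) holds by
construction.

All randomness flows through a single ``numpy.random.Generator`` derived from
``SimConfig.seed``; identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaussian import FWHM_FACTOR
from .volume import VolumeImage

NM_PER_UM = 1000.0


def sphere_area_um2(radius_nm: float) -> float:
    """Surface area 4*pi*r^2 of a sphere, in um^2."""
    r_um = radius_nm / NM_PER_UM
    return 4.0 * math.pi * r_um**2


@dataclass
class SimConfig:
    """Parameters of one simulated nucleus.

    Exactly one of ``n_npcs`` (a count) or ``density_per_um2`` (NPCs/um^2,
    converted to the nearest feasible count on the sphere) must be given.
    """

    radius_nm: float = 1250.0
    n_npcs: int | None = None
    density_per_um2: float | None = None
    min_spacing_nm: float = 100.0
    psf_fwhm_xy_nm: float = 100.0
    psf_fwhm_z_nm: float = 300.0
    peak_photons: float = 100.0
    gain: float = 20.0
    read_noise_sd: float = 40.0
    shot_noise: bool = True
    pixel_nm: float = 40.0
    zstep_nm: float = 125.0
    spb_separation_nm: float = 180.0
    spb_daughter_ratio: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be positive")
        if self.min_spacing_nm < 0:
            raise ValueError("min_spacing_nm must be >= 0")
        if (self.n_npcs is None) == (self.density_per_um2 is None):
            raise ValueError("give exactly one of n_npcs or density_per_um2")
        for name in ("peak_photons", "gain", "read_noise_sd", "pixel_nm", "zstep_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # Feasibility: hard-core discs must not exceed the sphere's area.
        n = self.resolved_n_npcs()
        disc = math.pi * (self.min_spacing_nm / 2.0) ** 2
        if n * disc > 4.0 * math.pi * self.radius_nm**2:
            raise ValueError(
                f"{n} points with {self.min_spacing_nm} nm spacing cannot pack "
                f"onto a sphere of radius {self.radius_nm} nm"
            )

    def resolved_n_npcs(self) -> int:
        if self.n_npcs is not None:
            return int(self.n_npcs)
        return int(round(self.density_per_um2 * sphere_area_um2(self.radius_nm)))

    @property
    def sigma_xy_nm(self) -> float:
        return self.psf_fwhm_xy_nm / FWHM_FACTOR

    @property
    def sigma_z_nm(self) -> float:
        return self.psf_fwhm_z_nm / FWHM_FACTOR

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FociTruth:
    """Ground-truth emitter positions for one nucleus.

    ``positions_nm`` is ``(n, 3)`` in (x, y, z); every position lies on the
    sphere of ``radius_nm`` around ``sphere_center_nm`` and all pairwise
    distances are at least the configured spacing.
    """

    positions_nm: np.ndarray
    intensities: np.ndarray
    sphere_center_nm: np.ndarray
    radius_nm: float

    @property
    def n(self) -> int:
        return len(self.positions_nm)

    @property
    def true_density_per_um2(self) -> float:
        return self.n / sphere_area_um2(self.radius_nm)


@dataclass
class SPBTruth:
    """Ground-truth landmark pair: mother (brighter) and daughter spots."""

    mother_nm: np.ndarray
    daughter_nm: np.ndarray
    mother_intensity: float
    daughter_intensity: float

    @property
    def separation_nm(self) -> float:
        return float(np.linalg.norm(self.mother_nm - self.daughter_nm))

    @property
    def midpoint_nm(self) -> np.ndarray:
        return 0.5 * (self.mother_nm + self.daughter_nm)


class PackingError(RuntimeError):
    pass


def _grid_geometry(config: SimConfig) -> tuple[tuple[int, int, int], np.ndarray]:
    """Auto-sized voxel grid: sphere diameter + 3x axial FWHM margin per side."""
    margin = 3.0 * config.psf_fwhm_z_nm
    extent = 2.0 * (config.radius_nm + margin)
    nx = int(math.ceil(extent / config.pixel_nm))
    nz = int(math.ceil(extent / config.zstep_nm))
    center = np.array([
        nx * config.pixel_nm / 2.0, nx * config.pixel_nm / 2.0, nz * config.zstep_nm / 2.0,
    ])
    return (nz, nx, nx), center


def sample_points_on_sphere(config: SimConfig,
                            rng: np.random.Generator | None = None,
                            max_attempts_per_point: int = 10_000,
                            forbidden_centers_nm: np.ndarray | None = None,
                            forbidden_radius_nm: float = 0.0) -> FociTruth:
    """Uniform points on the sphere with a hard minimum spacing.

    Rejection sampling: isotropic directions (normalised Gaussian triples)
    scaled to the radius; a candidate is kept only if it clears
    ``min_spacing_nm`` to every accepted point. Optional forbidden zones
    (absolute-frame centers + a common radius) support constructed exclusion
    zones, e.g. around the SPB. Raises :class:`PackingError` naming the
    achieved count if the budget is exhausted.
    """
    rng = config.rng() if rng is None else rng
    n = config.resolved_n_npcs()
    _, center = _grid_geometry(config)
    forb = None
    if forbidden_centers_nm is not None and forbidden_radius_nm > 0:
        forb = np.atleast_2d(np.asarray(forbidden_centers_nm, dtype=float))
    pts = np.empty((n, 3))
    min_sq = config.min_spacing_nm**2
    k = 0
    attempts = 0
    while k < n:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm == 0.0:
            continue
        cand = v / norm * config.radius_nm
        ok = k == 0 or np.min(np.sum((pts[:k] - cand) ** 2, axis=1)) >= min_sq
        if ok and forb is not None:
            ok = np.min(np.linalg.norm(forb - (cand + center), axis=1)) >= forbidden_radius_nm
        if ok:
            pts[k] = cand
            k += 1
            attempts = 0
        else:
            attempts += 1
            if attempts >= max_attempts_per_point:
                raise PackingError(
                    f"placed only {k}/{n} points at spacing "
                    f"{config.min_spacing_nm} nm on radius {config.radius_nm} nm"
                )
    return FociTruth(
        positions_nm=pts + center,
        intensities=np.full(n, config.peak_photons),
        sphere_center_nm=center,
        radius_nm=config.radius_nm,
    )


def render_volume(truth: FociTruth, config: SimConfig,
                  max_voxels: int = 200_000_000) -> VolumeImage:
    """Expected-photon image: a sum of anisotropic 3D Gaussians.

    Each emitter contributes ``peak * exp(-dx^2/2sx^2 - dy^2/2sy^2 - dz^2/2sz^2)``
    evaluated at voxel centers, truncated at 4.5 sigma per axis (truncated
    mass < 0.02%). Deterministic given the truth.
    """
    shape, _ = _grid_geometry(config)
    nz, ny, nx = shape
    if nz * ny * nx > max_voxels:
        raise ValueError(f"voxel grid {shape} exceeds cap of {max_voxels} voxels")
    img = np.zeros(shape, dtype=np.float64)
    sx = config.sigma_xy_nm
    sz = config.sigma_z_nm
    half_x = int(math.ceil(4.5 * sx / config.pixel_nm))
    half_z = int(math.ceil(4.5 * sz / config.zstep_nm))
    xc = (np.arange(nx) + 0.5) * config.pixel_nm
    zc = (np.arange(nz) + 0.5) * config.zstep_nm
    for (px, py, pz), amp in zip(truth.positions_nm, truth.intensities):
        ix = int(px / config.pixel_nm)
        iy = int(py / config.pixel_nm)
        iz = int(pz / config.zstep_nm)
        x0, x1 = max(ix - half_x, 0), min(ix + half_x + 1, nx)
        y0, y1 = max(iy - half_x, 0), min(iy + half_x + 1, ny)
        z0, z1 = max(iz - half_z, 0), min(iz + half_z + 1, nz)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        gx = np.exp(-0.5 * ((xc[x0:x1] - px) / sx) ** 2)
        gy = np.exp(-0.5 * ((xc[y0:y1] - py) / sx) ** 2)
        gz = np.exp(-0.5 * ((zc[z0:z1] - pz) / sz) ** 2)
        img[z0:z1, y0:y1, x0:x1] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return VolumeImage(img, pixel_nm=config.pixel_nm, zstep_nm=config.zstep_nm)


def apply_camera(photon_image: VolumeImage, config: SimConfig,
                 rng: np.random.Generator | None = None) -> VolumeImage:
    """Camera model: gain x (Poisson photons) + Gaussian read noise.

    ``output = gain * Poisson(expected) + N(0, read_noise_sd)`` per voxel;
    with ``shot_noise=False`` the Poisson draw is replaced by the expectation.
    """
    if np.any(photon_image.voxels < 0):
        raise ValueError("photon image must be non-negative")
    rng = config.rng() if rng is None else rng
    expected = photon_image.voxels
    photons = rng.poisson(expected).astype(np.float64) if config.shot_noise else expected
    out = config.gain * photons
    if config.read_noise_sd > 0:
        out = out + rng.normal(0.0, config.read_noise_sd, size=out.shape)
    return photon_image.with_voxels(out)


def sample_spb_pair(config: SimConfig, rng: np.random.Generator | None = None,
                    min_edge_nm: float = 400.0) -> SPBTruth:
    """Place the SPB landmark pair in the top polar cap.

    The pair midpoint sits on the sphere at a polar angle small enough that
    both projected spots stay at least ``min_edge_nm`` (plus a 60 nm safety
    margin) inside the projected nuclear rim; the pair axis is tangent to the
    sphere with a uniform in-plane orientation. The mother spot is the
    brighter one.
    """
    rng = config.rng() if rng is None else rng
    r = config.radius_nm
    half_sep = config.spb_separation_nm / 2.0
    sin_max = (r - min_edge_nm - half_sep - 60.0) / r
    if sin_max <= 0:
        raise ValueError(
            f"radius {r} nm cannot satisfy the {min_edge_nm} nm edge margin"
        )
    _, center = _grid_geometry(config)
    # Uniform over the admissible cap: cos(theta) uniform on [cos(theta_max), 1].
    cos_max = math.sqrt(1.0 - sin_max**2)
    cos_t = rng.uniform(cos_max, 1.0)
    sin_t = math.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    mid = r * np.array([sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t])
    normal = mid / r
    # Orthonormal tangent basis at the midpoint; random in-plane axis direction.
    helper = np.array([0.0, 0.0, 1.0])
    if abs(normal[2]) > 0.999:
        helper = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(normal, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    ang = rng.uniform(0.0, 2.0 * math.pi)
    axis = math.cos(ang) * t1 + math.sin(ang) * t2
    mother = mid + half_sep * axis + center
    daughter = mid - half_sep * axis + center
    return SPBTruth(
        mother_nm=mother, daughter_nm=daughter,
        mother_intensity=config.peak_photons,
        daughter_intensity=config.spb_daughter_ratio * config.peak_photons,
    )


def add_spb_channel(truth: FociTruth, config: SimConfig,
                    rng: np.random.Generator | None = None,
                    min_edge_nm: float = 400.0,
                    noise: bool = True) -> tuple[SPBTruth, VolumeImage]:
    """Render the SPB landmark pair as a second channel.

    Same PSF, grid and camera model as the NPC channel (``noise=False``
    returns the expected-photon image).
    """
    rng = config.rng() if rng is None else rng
    spb = sample_spb_pair(config, rng, min_edge_nm=min_edge_nm)
    spb_truth = FociTruth(
        positions_nm=np.stack([spb.mother_nm, spb.daughter_nm]),
        intensities=np.array([spb.mother_intensity, spb.daughter_intensity]),
        sphere_center_nm=truth.sphere_center_nm,
        radius_nm=truth.radius_nm,
    )
    vol = render_volume(spb_truth, config)
    if noise:
        vol = apply_camera(vol, config, rng)
    vol.channel = "spb"
    return spb, vol


def simulate_nucleus(config: SimConfig, rng: np.random.Generator | None = None,
                     spb: bool = False):
    """Convenience: sample truth, render, apply camera (optionally + SPB channel).

    Returns ``(truth, volume)`` or ``(truth, volume, spb_truth, spb_volume)``.
    """
    rng = config.rng() if rng is None else rng
    truth = sample_points_on_sphere(config, rng)
    vol = apply_camera(render_volume(truth, config), config, rng)
    vol.channel = "npc"
    if not spb:
        return truth, vol
    spb_truth, spb_vol = add_spb_channel(truth, config, rng)
    return truth, vol, spb_truth, spb_vol


def generate_condition_grid(radii_nm, densities_per_um2, n_per_condition: int,
                            seed: int = 0) -> pd.DataFrame:
    """Manifest for a radius x density simulation grid.

    One row per image with a deterministic child seed spawned from the master
    seed, the true count (density rounded onto the sphere), the exact true
    density ``n / 4 pi r^2`` and the analytic surface area. Rendering is left
    to the caller (see ``analysis/01_simulate_grid.py``) so the manifest stays
    cheap to build and test.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    n_images = len(radii_nm) * len(densities_per_um2) * n_per_condition
    child_seeds = ss.generate_state(n_images) % (2**31)
    i = 0
    for r in radii_nm:
        sa = sphere_area_um2(r)
        for d in densities_per_um2:
            n_npcs = int(round(d * sa))
            for rep in range(n_per_condition):
                rows.append({
                    "image_id": f"r{int(r)}_d{d:g}_rep{rep:03d}",
                    "seed": int(child_seeds[i]),
                    "radius_nm": float(r),
                    "target_density_per_um2": float(d),
                    "n_npcs": n_npcs,
                    "true_density_per_um2": n_npcs / sa,
                    "true_sa_um2": sa,
                })
                i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nucleolar two-channel scene (test substrate for the NE line-profile module)
# ---------------------------------------------------------------------------

@dataclass
class NucleolarScene:
    """A synthetic NE arc-profile pair with a nucleolar Nup reduction.

    ``positions_nm`` runs along the circular NE trace; ``nup`` is flat at 1
    except over the nucleolar arc, where it is scaled by ``1 - reduction``;
    ``marker`` is a smooth bump whose half-max run covers exactly that arc.
    The scene is rotated by a random angle so alignment is actually exercised.
    """

    positions_nm: np.ndarray
    nup: np.ndarray
    marker: np.ndarray
    ne_radius_nm: float
    nucleolar_arc_deg: float
    nup_reduction_frac: float
    rotation_deg: float
    pixel_nm: float

    def render(self, ring_sigma_nm: float = 80.0, margin_nm: float = 400.0):
        """Rasterise the scene to a 2-channel 2D image plus the NE polyline.

        Returns ``(image (2, ny, nx), polyline (m, 2) in pixel (x, y))``.
        The ring has a Gaussian radial cross-section; angular intensity
        follows the channel profiles.
        """
        r = self.ne_radius_nm
        px = self.pixel_nm
        half = r + margin_nm
        n_side = int(math.ceil(2 * half / px))
        c = n_side * px / 2.0
        coords = (np.arange(n_side) + 0.5) * px - c
        xx, yy = np.meshgrid(coords, coords)
        rho = np.hypot(xx, yy)
        theta = np.arctan2(yy, xx)  # [-pi, pi]
        radial = np.exp(-0.5 * ((rho - r) / ring_sigma_nm) ** 2)
        # Interpolate each channel's angular profile at the pixel angles.
        n_samp = len(self.nup)
        samp_theta = (np.arange(n_samp) + 0.5) / n_samp * 2 * math.pi - math.pi
        img = np.empty((2, n_side, n_side))
        for ci, prof in enumerate((self.nup, self.marker)):
            ang = np.interp(theta.ravel(), samp_theta, prof,
                            period=2 * math.pi).reshape(theta.shape)
            img[ci] = ang * radial
        poly_theta = samp_theta
        poly = np.stack([(r * np.cos(poly_theta) + c) / px - 0.5,
                         (r * np.sin(poly_theta) + c) / px - 0.5], axis=1)
        return img, poly


def generate_nucleolar_scene(ne_radius_nm: float = 1250.0,
                             nucleolar_arc_deg: float = 120.0,
                             nup_reduction_frac: float = 0.2,
                             noise_sd: float = 0.0,
                             seed: int | None = None,
                             pixel_nm: float = 40.0) -> NucleolarScene:
    """Build one synthetic two-channel NE profile pair with known truth.

    The Nup channel is 1 everywhere except the nucleolar arc, where it is
    ``1 - nup_reduction_frac``; the marker bump is ``cos^2`` shaped with its
    half-max run exactly spanning that arc (so half-max alignment centres on
    the arc midpoint by construction). Gaussian noise of SD ``noise_sd``
    (fraction of the flank level) is added independently per sample.
    """
    if not 0.0 <= nup_reduction_frac <= 1.0:
        raise ValueError("nup_reduction_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    circumference = 2 * math.pi * ne_radius_nm
    n = int(round(circumference / pixel_nm))
    theta = (np.arange(n) + 0.5) / n * 2 * math.pi - math.pi
    rot = rng.uniform(-math.pi, math.pi)
    arc = math.radians(nucleolar_arc_deg)
    # Shortest signed angular distance from the nucleolus centre.
    d = np.angle(np.exp(1j * (theta - rot)))
    nup = np.where(np.abs(d) <= arc / 2.0, 1.0 - nup_reduction_frac, 1.0)
    # cos^2 bump, support |d| < arc, half-max exactly at |d| = arc/2.
    marker = np.where(np.abs(d) < arc, np.cos(np.pi * d / (2 * arc)) ** 2, 0.0)
    if noise_sd > 0:
        nup = nup + rng.normal(0.0, noise_sd, n)
        marker = marker + rng.normal(0.0, noise_sd, n)
    positions = (np.arange(n) + 0.5) * (circumference / n)
    return NucleolarScene(
        positions_nm=positions, nup=nup, marker=marker,
        ne_radius_nm=ne_radius_nm, nucleolar_arc_deg=nucleolar_arc_deg,
        nup_reduction_frac=nup_reduction_frac, rotation_deg=math.degrees(rot),
        pixel_nm=pixel_nm,
    )
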