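"""Nup intensity along the NE relative to the nucleolar marker.

Per-nucleus two-channel line profiles traced along the NE are anchored on the
nucleolar marker: the marker profile is boxcar-smoothed, thresholded at half
its maximum, and the midpoint of the above-threshold run defines position 0.
All Nup profiles are shifted to that anchor, resampled onto a common grid and
averaged; the headline number is the mean normalised Nup intensity at
position 0 — the depth of the nucleolar reduction in NPC signal.

Profiles from closed (circular) traces are treated as periodic, so the
marker run may wrap around the trace start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class NEProfilePair:
    """Arc-length positions (nm) with Nup and marker intensities for one nucleus."""

    positions_nm: np.ndarray
    nup: np.ndarray
    marker: np.ndarray
    nucleus_id: str = ""
    periodic: bool = True

    def __post_init__(self) -> None:
        if not (len(self.positions_nm) == len(self.nup) == len(self.marker)):
            raise ValueError("positions, nup and marker must have equal length")
        if np.any(np.diff(self.positions_nm) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class AlignedProfileSet:
    """Marker-anchored, resampled Nup profiles on a common grid (0 = marker centre)."""

    grid_nm: np.ndarray
    profiles: np.ndarray          # (n_nuclei, n_grid), normalised
    mean_profile: np.ndarray
    sd_profile: np.ndarray
    nucleus_ids: list[str]
    dropped: list[tuple[str, str]]  # (nucleus id, reason)

    @property
    def n(self) -> int:
        return len(self.profiles)


def extract_profile_pair(image: np.ndarray, polyline_px: np.ndarray,
                         pixel_nm: float, width_px: int = 3,
                         nucleus_id: str = "", periodic: bool = True) -> NEProfilePair:
    """Banded two-channel line profile along an NE trace.

    ``image`` is ``(2, ny, nx)`` (Nup, marker); ``polyline_px`` is ``(m, 2)``
    vertices in pixel (x, y). At each vertex the intensity is averaged over a
    ``width_px``-pixel band perpendicular to the local path direction
    (bilinear sampling). Arc length is reported in nm.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[0] != 2:
        raise ValueError("image must be (2, ny, nx)")
    poly = np.asarray(polyline_px, dtype=float)
    ny, nx = img.shape[1:]
    if (poly[:, 0].min() < -0.5 or poly[:, 0].max() > nx - 0.5
            or poly[:, 1].min() < -0.5 or poly[:, 1].max() > ny - 0.5):
        raise ValueError("polyline extends outside the image")
    # Local tangents (central differences; wrapped when periodic).
    if periodic:
        tang = np.roll(poly, -1, axis=0) - np.roll(poly, 1, axis=0)
    else:
        tang = np.gradient(poly, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang /= norms
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    samples = poly[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    rows = samples[..., 1].ravel()
    cols = samples[..., 0].ravel()
    profs = []
    for ch in range(2):
        vals = ndimage.map_coordinates(img[ch], [rows, cols], order=1, mode="nearest")
        profs.append(vals.reshape(len(poly), width_px).mean(axis=1))
    step = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    positions = np.concatenate([[0.0], np.cumsum(step)]) * pixel_nm
    return NEProfilePair(positions_nm=positions, nup=profs[0], marker=profs[1],
                         nucleus_id=nucleus_id, periodic=periodic)


def _marker_run(marker_smooth: np.ndarray, periodic: bool) -> tuple[int, int] | None:
    """Longest above-half-max run; (start, length) with wrap-around indices."""
    half = marker_smooth.max() / 2.0
    above = marker_smooth > half
    if not above.any():
        return None
    n = len(above)
    if above.all():
        return 0, n
    if periodic:
        # rotate so index 0 is below threshold, find runs, rotate back
        first_below = int(np.argmin(above))
        rolled = np.roll(above, -first_below)
    else:
        first_below = 0
        rolled = above
    edges = np.diff(rolled.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if rolled[0]:
        starts = np.concatenate([[0], starts])
    if rolled[-1]:
        ends = np.concatenate([ends, [n]])
    lengths = ends - starts
    k = int(np.argmax(lengths))
    return (int(starts[k]) + first_below) % n, int(lengths[k])


def align_and_average(pairs: list[NEProfilePair], boxcar_w: int = 5,
                      grid_nm: float | None = None,
                      normalize: bool = True,
                      dilate_steps: int = 2) -> AlignedProfileSet:
    """Anchor every profile at the marker-peak centre and average.

    Per nucleus: boxcar-smooth the marker (width ``boxcar_w``), find the
    above-half-max run, take its midpoint as position 0, resample the Nup
    profile onto a common uniform grid by linear interpolation, and normalise
    it by its mean intensity *outside* the marker run (dilated by
    ``dilate_steps`` grid steps). Nuclei with no detectable marker run are
    dropped with a logged reason. ``grid_nm`` defaults to the median sample
    spacing of the inputs.
    """
    if not pairs:
        raise ValueError("no profiles to align")
    if grid_nm is None:
        grid_nm = float(np.median([np.median(np.diff(p.positions_nm)) for p in pairs]))
    half_span = min(float(p.positions_nm[-1] - p.positions_nm[0]) for p in pairs) / 2.0
    # symmetric grid containing exactly 0, covering half the shortest trace
    n_half = int(half_span / 2.0 / grid_nm)
    grid = np.arange(-n_half, n_half + 1) * grid_nm

    profiles = []
    ids = []
    dropped: list[tuple[str, str]] = []
    for p in pairs:
        kernel = np.ones(boxcar_w) / boxcar_w
        if p.periodic:
            smooth = np.convolve(np.concatenate([p.marker[-boxcar_w:], p.marker,
                                                 p.marker[:boxcar_w]]), kernel,
                                 mode="same")[boxcar_w:-boxcar_w]
        else:
            smooth = np.convolve(p.marker, kernel, mode="same")
        if smooth.max() <= 0:
            dropped.append((p.nucleus_id, "marker channel empty"))
            continue
        run = _marker_run(smooth, p.periodic)
        if run is None:
            dropped.append((p.nucleus_id, "no above-half-max marker run"))
            continue
        start, length = run
        n = len(p.nup)
        center_idx = (start + (length - 1) / 2.0) % n
        if p.periodic:
            # roll so the run centre sits mid-array, then build relative positions
            shift = int(round(n / 2.0 - center_idx))
            nup = np.roll(p.nup, shift)
            run_center = (center_idx + shift) % n
            spacing = np.median(np.diff(p.positions_nm))
            rel = (np.arange(n) - run_center) * spacing
            in_run = np.abs((np.arange(n) - run_center)) <= (length / 2.0 + dilate_steps)
        else:
            nup = p.nup
            spacing = np.median(np.diff(p.positions_nm))
            rel = p.positions_nm - np.interp(center_idx, np.arange(n), p.positions_nm)
            in_run = np.abs(np.arange(n) - center_idx) <= (length / 2.0 + dilate_steps)
        if normalize:
            ref = nup[~in_run]
            if ref.size == 0 or ref.mean() == 0:
                dropped.append((p.nucleus_id, "no normalisation reference outside marker"))
                continue
            nup = nup / ref.mean()
        profiles.append(np.interp(grid, rel, nup))
        ids.append(p.nucleus_id)
    if not profiles:
        raise ValueError(f"all {len(pairs)} nuclei dropped: {dropped}")
    arr = np.asarray(profiles)
    return AlignedProfileSet(
        grid_nm=grid, profiles=arr,
        mean_profile=arr.mean(axis=0), sd_profile=arr.std(axis=0, ddof=1) if len(arr) > 1
        else np.zeros(arr.shape[1]),
        nucleus_ids=ids, dropped=dropped,
    )


def nup_reduction_at_center(aligned: AlignedProfileSet) -> tuple[float, float]:
    """Mean (+ SD over nuclei) normalised Nup intensity at position 0.

    1.0 means no reduction over the nucleolus; 0.8 means a 20% reduction.
    """
    i0 = int(np.argmin(np.abs(aligned.grid_nm)))
    vals = aligned.profiles[:, i0]
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd
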