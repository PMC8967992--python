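"""Per-nucleus summaries: count, surface area, density, co-detection,
intensity per unit surface area."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .detect import FociSet
from .hull import HullResult
from .segment import NucleusMask
from .volume import VolumeImage


@dataclass
class NucleusRecord:
    """One nucleus's headline numbers. ``density = count / surface_area`` exactly."""

    npc_count: int
    surface_area_um2: float
    volume_um3: float
    density_per_um2: float
    intensity_per_area: float | None = None
    stage: str | None = None


def summarize_nucleus(foci: FociSet, hull: HullResult,
                      count_retained_only: bool = False,
                      intensity_per_area: float | None = None,
                      stage: str | None = None) -> NucleusRecord:
    """Combine a detection set and its hull into a NucleusRecord.

    By default the count includes every detected focus, including any the
    hull optimiser removed (those removals refine the *surface model*, not
    the census); ``count_retained_only`` restricts the count to hull-retained
    points.
    """
    count = len(hull.retained_indices) if count_retained_only else foci.n
    return NucleusRecord(
        npc_count=count,
        surface_area_um2=hull.surface_area_um2,
        volume_um3=hull.volume_um3,
        density_per_um2=count / hull.surface_area_um2,
        intensity_per_area=intensity_per_area,
        stage=stage,
    )


@dataclass
class CodetectResult:
    """Two-channel co-detection at a distance threshold (default 250 nm)."""

    fraction_a: float | None   # None when channel A is empty (undefined)
    fraction_b: float | None
    codetected_a: np.ndarray   # boolean per point of A
    codetected_b: np.ndarray
    radius_nm: float


def codetect(foci_a: FociSet, foci_b: FociSet, radius_nm: float = 250.0) -> CodetectResult:
    """Fraction of foci in each channel with a partner within ``radius_nm``.

    Matching is many-to-one: a point is co-detected iff *any* point of the
    other channel lies within the radius. Empty channels give an undefined
    (None) fraction rather than zero.
    """

    def one_way(src: FociSet, other: FociSet) -> tuple[float | None, np.ndarray]:
        if src.n == 0:
            return None, np.zeros(0, dtype=bool)
        if other.n == 0:
            return 0.0, np.zeros(src.n, dtype=bool)
        tree = cKDTree(other.coordinates_nm)
        dist, _ = tree.query(src.coordinates_nm, k=1)
        hit = dist <= radius_nm
        return float(hit.mean()), hit

    fa, hits_a = one_way(foci_a, foci_b)
    fb, hits_b = one_way(foci_b, foci_a)
    return CodetectResult(fa, fb, hits_a, hits_b, radius_nm)


def intensity_per_area(raw_volume: VolumeImage, mask: NucleusMask,
                       surface_area_um2: float,
                       background: float | None = None) -> float:
    """Background-subtracted integrated intensity per um^2 of NE surface.

    The stack is sum-projected; the background (per projected pixel) defaults
    to the median of pixels outside the nucleus mask; the subtracted signal is
    integrated over the mask and divided by the hull surface area.
    """
    if surface_area_um2 <= 0:
        raise ValueError("surface area must be positive")
    proj = raw_volume.sum_projection()
    if background is None:
        outside = proj[~mask.mask]
        background = float(np.median(outside)) if outside.size else 0.0
    signal = float((proj[mask.mask] - background).sum())
    return signal / surface_area_um2
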