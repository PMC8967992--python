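"""Calibrated 3D volumes and TIFF round-tripping.

A :class:`VolumeImage` is the raster currency of the pipeline: a ``(nz, ny,
nx)`` intensity array plus the physical calibration (lateral pixel size and
axial z-step, both in nm). Point coordinates throughout the package are
``(x, y, z)`` in nm, with the origin at the volume corner and voxel centers
at ``(i + 0.5) * pitch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class VolumeImage:
    """A single-channel 3D image with physical calibration.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensity raster.
    pixel_nm : float
        Lateral voxel size (x and y), nm.
    zstep_nm : float
        Axial spacing between slices, nm.
    channel : str
        Free-text channel label.
    """

    voxels: np.ndarray
    pixel_nm: float
    zstep_nm: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.voxels.ndim}")
        if not (self.pixel_nm > 0 and self.zstep_nm > 0):
            raise ValueError("calibration must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical (x, y, z) extent in nm."""
        nz, ny, nx = self.voxels.shape
        return (nx * self.pixel_nm, ny * self.pixel_nm, nz * self.zstep_nm)

    def voxel_to_nm(self, indices: np.ndarray) -> np.ndarray:
        """Convert ``(iz, iy, ix)`` voxel indices to ``(x, y, z)`` nm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        out = np.empty_like(idx)
        out[:, 0] = (idx[:, 2] + 0.5) * self.pixel_nm
        out[:, 1] = (idx[:, 1] + 0.5) * self.pixel_nm
        out[:, 2] = (idx[:, 0] + 0.5) * self.zstep_nm
        return out if np.asarray(indices).ndim > 1 else out[0]

    def nm_to_voxel(self, coords: np.ndarray) -> np.ndarray:
        """Convert ``(x, y, z)`` nm coordinates to fractional ``(iz, iy, ix)`` indices."""
        xyz = np.atleast_2d(np.asarray(coords, dtype=float))
        out = np.empty_like(xyz)
        out[:, 0] = xyz[:, 2] / self.zstep_nm - 0.5
        out[:, 1] = xyz[:, 1] / self.pixel_nm - 0.5
        out[:, 2] = xyz[:, 0] / self.pixel_nm - 0.5
        return out if np.asarray(coords).ndim > 1 else out[0]

    def max_projection(self) -> np.ndarray:
        return self.voxels.max(axis=0)

    def sum_projection(self) -> np.ndarray:
        return self.voxels.sum(axis=0)

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        return replace(self, voxels=voxels)


def write_volume(path, volumes: VolumeImage | list[VolumeImage]) -> None:
    """Write one or more channels to an ImageJ-style TIFF with calibration.

    Multi-channel data is stored as a (z, c, y, x) hyperstack. Calibration is
    recorded in the ImageJ metadata block (``spacing`` in um) and the TIFF
    resolution tags, so :func:`read_volume` round-trips it without side files.
    """
    if isinstance(volumes, VolumeImage):
        volumes = [volumes]
    pixel_nm = volumes[0].pixel_nm
    zstep_nm = volumes[0].zstep_nm
    for v in volumes[1:]:
        if v.pixel_nm != pixel_nm or v.zstep_nm != zstep_nm or v.shape != volumes[0].shape:
            raise ValueError("all channels must share shape and calibration")
    stack = np.stack([v.voxels for v in volumes], axis=1).astype(np.float32)  # (z, c, y, x)
    px_um = pixel_nm / 1000.0
    tifffile.imwrite(
        path,
        stack,
        imagej=True,
        resolution=(1.0 / px_um, 1.0 / px_um),
        metadata={
            "spacing": zstep_nm / 1000.0,
            "unit": "um",
            "axes": "ZCYX",
            "Labels": [v.channel for v in volumes],
        },
    )


def read_volume(path, channel: int = 0, pixel_nm: float | None = None,
                zstep_nm: float | None = None) -> VolumeImage:
    """Read one channel of a TIFF stack with its calibration.

    Calibration comes from the ImageJ metadata / resolution tags unless
    overridden. Raises a clear error when no calibration can be found and no
    override is given.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        series = tif.series[0]
        axes = series.axes
        meta = tif.imagej_metadata or {}
        if pixel_nm is None:
            try:
                xres = tif.pages[0].tags["XResolution"].value
                pixel_nm = xres[1] / xres[0] * 1000.0  # px per um -> nm per px
            except (KeyError, ZeroDivisionError):
                pixel_nm = None
        if zstep_nm is None:
            spacing = meta.get("spacing")
            zstep_nm = spacing * 1000.0 if spacing else None
    if pixel_nm is None or zstep_nm is None:
        raise ValueError(
            f"{path}: missing voxel calibration; pass pixel_nm/zstep_nm "
            "(CLI: --pixel-nm / --zstep-nm)"
        )
    arr = np.asarray(arr)
    if "C" in axes:
        arr = np.moveaxis(arr, axes.index("C"), 1)
        if channel >= arr.shape[1]:
            raise ValueError(f"channel {channel} not in file with {arr.shape[1]} channels")
        arr = arr[:, channel]
    elif channel != 0:
        raise ValueError(f"channel {channel} requested from a single-channel file")
    if arr.ndim == 2:
        arr = arr[None]
    return VolumeImage(arr.astype(np.float64), pixel_nm=pixel_nm, zstep_nm=zstep_nm)
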