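"""Batch plumbing: configs, manifests and CSV/TIFF round-trips for the CLI.

Every output CSV carries a header comment with the package version and a hash
of the run configuration, so results are traceable to their exact settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detect import DetectionParams, FociSet, detect_foci
from .hull import fit_hull
from .quantify import summarize_nucleus
from .segment import SegmentationParams, segment_nuclei
from .simulate import SimConfig, apply_camera, render_volume, sample_points_on_sphere
from .volume import VolumeImage, write_volume


def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv_with_header(df: pd.DataFrame, path, config: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# npcquant {__version__} config_hash={config_hash(config)}\n")
        df.to_csv(fh, index=False)


def read_csv_with_header(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def foci_to_frame(foci: FociSet, nucleus_id: str = "") -> pd.DataFrame:
    return pd.DataFrame({
        "nucleus_id": nucleus_id,
        "x_nm": foci.coordinates_nm[:, 0],
        "y_nm": foci.coordinates_nm[:, 1],
        "z_nm": foci.coordinates_nm[:, 2],
        "intensity": foci.intensities,
    })


def frame_to_foci(df: pd.DataFrame) -> FociSet:
    return FociSet(
        coordinates_nm=df[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
        intensities=df["intensity"].to_numpy(float) if "intensity" in df
        else np.ones(len(df)),
    )


def simulate_to_tiff(config: SimConfig, out_path, spb: bool = False) -> dict:
    """Simulate one nucleus and write it as a calibrated TIFF; returns truth info.

    The full simulation config is written alongside as ``<stem>.config.yaml``.
    """
    import yaml

    rng = config.rng()
    truth = sample_points_on_sphere(config, rng)
    vol = apply_camera(render_volume(truth, config), config, rng)
    vol.channel = "npc"
    channels = [vol]
    info = {
        "seed": config.seed,
        "radius_nm": config.radius_nm,
        "n_npcs": truth.n,
        "true_density_per_um2": truth.true_density_per_um2,
        "true_sa_um2": 4.0 * np.pi * (config.radius_nm / 1000.0) ** 2,
    }
    if spb:
        from .simulate import add_spb_channel
        spb_truth, spb_vol = add_spb_channel(truth, config, rng)
        channels.append(spb_vol)
        info["spb_separation_nm"] = spb_truth.separation_nm
    write_volume(out_path, channels)
    Path(out_path).with_suffix(".config.yaml").write_text(
        yaml.safe_dump({"config": asdict(config), **info}, sort_keys=False))
    return info


def count_volume(volume: VolumeImage,
                 seg_params: SegmentationParams | None = None,
                 det_params: DetectionParams | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment all nuclei in a volume and quantify each: (records, foci) frames."""
    masks = segment_nuclei(volume.max_projection(), volume.pixel_nm, seg_params)
    records = []
    foci_frames = []
    for i, mask in enumerate(masks):
        nucleus_id = f"nucleus{i:03d}"
        foci = detect_foci(volume, mask, det_params)
        foci_frames.append(foci_to_frame(foci, nucleus_id))
        if foci.n < 4:
            continue
        hull = fit_hull(foci.coordinates_nm)
        rec = summarize_nucleus(foci, hull)
        records.append({
            "nucleus_id": nucleus_id,
            "npc_count": rec.npc_count,
            "surface_area_um2": rec.surface_area_um2,
            "volume_um3": rec.volume_um3,
            "density_per_um2": rec.density_per_um2,
            "on_hull_fraction": hull.on_hull_fraction,
            "n_removed": hull.n_removed,
        })
    records_df = pd.DataFrame(records)
    foci_df = (pd.concat(foci_frames, ignore_index=True) if foci_frames
               else pd.DataFrame(columns=["nucleus_id", "x_nm", "y_nm", "z_nm",
                                          "intensity"]))
    return records_df, foci_df
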