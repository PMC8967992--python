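import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from npcquant.simulate import SimConfig, apply_camera, render_volume, sample_points_on_sphere


@pytest.fixture(scope="session")
def default_config():
    """The standard simulated nucleus: 125 NPCs on a 1.25 um sphere."""
    return SimConfig(n_npcs=125, seed=42)


@pytest.fixture(scope="session")
def simulated_nucleus(default_config):
    """(truth, noisy volume) for the standard nucleus; shared across tests."""
    rng = default_config.rng()
    truth = sample_points_on_sphere(default_config, rng)
    vol = apply_camera(render_volume(truth, default_config), default_config, rng)
    return truth, vol


@pytest.fixture(scope="session")
def noiseless_single_emitter():
    """One emitter rendered without noise, centred on a known voxel."""
    cfg = SimConfig(radius_nm=600.0, n_npcs=1, seed=0, shot_noise=False,
                    read_noise_sd=0.0)
    from npcquant.simulate import FociTruth, _grid_geometry
    shape, center = _grid_geometry(cfg)
    # put the emitter exactly on a voxel center near the middle of the grid
    iz, iy, ix = shape[0] // 2, shape[1] // 2, shape[2] // 2
    pos = np.array([(ix + 0.5) * cfg.pixel_nm, (iy + 0.5) * cfg.pixel_nm,
                    (iz + 0.5) * cfg.zstep_nm])
    truth = FociTruth(positions_nm=pos[None, :], intensities=np.array([100.0]),
                      sphere_center_nm=center, radius_nm=cfg.radius_nm)
    vol = render_volume(truth, cfg)
    return cfg, truth, vol, (iz, iy, ix)
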