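"""Shared fixtures: small ground-truthed synthetic inputs."""

import numpy as np
import pandas as pd
import pytest

from nucleodyn import synth
from nucleodyn.types import IntensityVolume, NuclearMask


def make_locs(xyz_nm: np.ndarray, frames=None, ids=None,
              sigma_xy: float = 0.0, sigma_z: float = 0.0) -> pd.DataFrame:
    """Build a localization table from an (n, 3) array of (x, y, z) nm."""
    xyz_nm = np.asarray(xyz_nm, dtype=float)
    n = len(xyz_nm)
    return pd.DataFrame({
        "id": np.zeros(n, dtype=int) if ids is None else np.asarray(ids),
        "frame": np.arange(n) if frames is None else np.asarray(frames),
        "x_nm": xyz_nm[:, 0],
        "y_nm": xyz_nm[:, 1],
        "z_nm": xyz_nm[:, 2],
        "sigma_xy_nm": sigma_xy,
        "sigma_z_nm": sigma_z,
    })


@pytest.fixture(scope="session")
def phantom_volume():
    """A small 7-class chromatin phantom with its ground truth."""
    gt = synth.VolumeGroundTruth(shape=(20, 56, 56), seed=11)
    vol, labels = synth.simulate_chromatin_volume(gt)
    mask = NuclearMask(labels > 0, voxel_size=gt.voxel_size, provenance="synthetic")
    return gt, vol, labels, mask


@pytest.fixture(scope="session")
def delta_psf():
    k = np.zeros((5, 5, 5))
    k[2, 2, 2] = 1.0
    return IntensityVolume(k, voxel_size=(110.0, 110.0, 110.0))


@pytest.fixture(scope="session")
def gaussian_psf():
    zz, yy, xx = np.mgrid[-4:5, -4:5, -4:5]
    k = np.exp(-(xx**2 + yy**2) / (2 * 1.5**2) - zz**2 / (2 * 2.0**2))
    return IntensityVolume(k / k.sum(), voxel_size=(110.0, 110.0, 110.0))
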