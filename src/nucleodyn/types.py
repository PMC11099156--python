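"""Shared containers for volumes, masks, and label maps.

Conventions used throughout the package:

* all physical coordinates and distances are in **nanometres**; MSDs and
  diffusion coefficients are in **µm²** / **µm²·s^−α** (the unit boundary is
  crossed only inside :mod:`nucleodyn.tracking` and noted there);
* voxel grids are indexed ``(z, y, x)`` and ``voxel_size`` is given in the
  same order, in nm per voxel;
* localization tables are plain :class:`pandas.DataFrame` objects with the
  column contract in :data:`LOC_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column contract for localization tables.  ``id`` is a trajectory id for
#: tracking data or a molecule id for SMLM data; positions are nm.
LOC_COLUMNS = ("id", "frame", "x_nm", "y_nm", "z_nm", "sigma_xy_nm", "sigma_z_nm")


def validate_localizations(locs: pd.DataFrame) -> pd.DataFrame:
    """Check the localization-table column contract and return the table."""
    missing = [c for c in LOC_COLUMNS if c not in locs.columns]
    if missing:
        raise ValueError(f"localization table missing columns: {missing}")
    return locs


@dataclass
class IntensityVolume:
    """A 3D non-negative intensity grid with physical voxel size.

    Parameters
    ----------
    data:
        3D array, indexed ``(z, y, x)``.
    voxel_size:
        nm per voxel along ``(z, y, x)``.  The live-cell default used in this
        package is ``(250, 110, 110)``; SMLM histogram renderings use
        ``(110, 110, 110)``.
    origin:
        nm offset of the voxel-grid origin (corner of voxel ``(0, 0, 0)``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (250.0, 110.0, 110.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("IntensityVolume.data must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("IntensityVolume contains non-finite values")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in µm³."""
        vz, vy, vx = self.voxel_size
        return (vz * vy * vx) * 1e-9


@dataclass
class NuclearMask:
    """Boolean nuclear support grid (single connected component)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (250.0, 110.0, 110.0)
    provenance: str = "otsu"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("NuclearMask.data must be 3D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class DistanceMap:
    """Per-voxel distance (nm) from foreground voxels to nearest background."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (250.0, 110.0, 110.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)


@dataclass
class CDCMap:
    """Integer chromatin-density-class labels per voxel.

    Labels: 0 = background, 1..K ordered by increasing class mean intensity
    (CDC1 = sparsest chromatin, CDCK = densest).
    """

    labels: np.ndarray
    K: int
    voxel_size: tuple[float, float, float] = (250.0, 110.0, 110.0)
    provenance: str = "real"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 3:
            raise ValueError("CDCMap.labels must be 3D")
        if self.labels.max(initial=0) > self.K:
            raise ValueError("label exceeds K")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def class_mask(self, c: int) -> np.ndarray:
        return self.labels == c


@dataclass
class RegionPartition:
    """Disjoint periphery / interior partition of the nuclear foreground."""

    periphery: np.ndarray
    interior: np.ndarray
    cutoff_nm: float = 500.0

    def __post_init__(self) -> None:
        self.periphery = np.asarray(self.periphery, dtype=bool)
        self.interior = np.asarray(self.interior, dtype=bool)
        if self.periphery.shape != self.interior.shape:
            raise ValueError("partition grids must share a shape")
        if np.any(self.periphery & self.interior):
            raise ValueError("periphery and interior overlap")
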