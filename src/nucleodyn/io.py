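"""Reading and writing the package's on-disk formats.

Localization and trajectory tables travel as CSV with the
:data:`nucleodyn.types.LOC_COLUMNS` contract; volumes as multi-page TIFF
with a JSON sidecar carrying voxel size and origin; label maps as 8-bit
TIFF; ground truth and fits as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import CDCMap, IntensityVolume, NuclearMask, validate_localizations


def write_localizations(locs: pd.DataFrame, path: str | Path) -> None:
    validate_localizations(locs).to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    return validate_localizations(pd.read_csv(path))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: IntensityVolume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32))
    _sidecar(path).write_text(json.dumps({
        "voxel_size_nm_zyx": list(vol.voxel_size),
        "origin_nm_zyx": list(vol.origin),
    }))


def read_volume(path: str | Path) -> IntensityVolume:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return IntensityVolume(data, voxel_size=tuple(meta["voxel_size_nm_zyx"]),
                           origin=tuple(meta["origin_nm_zyx"]))


def write_mask(mask: NuclearMask, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.data.astype(np.uint8))
    _sidecar(path).write_text(json.dumps({
        "voxel_size_nm_zyx": list(mask.voxel_size),
        "provenance": mask.provenance,
    }))


def write_cdc(cdc: CDCMap, path: str | Path) -> None:
    if cdc.K > 255:
        raise ValueError("more than 255 classes will not fit 8-bit TIFF")
    path = Path(path)
    tifffile.imwrite(path, cdc.labels.astype(np.uint8))
    _sidecar(path).write_text(json.dumps({
        "K": cdc.K,
        "voxel_size_nm_zyx": list(cdc.voxel_size),
        "provenance": cdc.provenance,
    }))


def read_cdc(path: str | Path) -> CDCMap:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    meta = json.loads(_sidecar(path).read_text())
    return CDCMap(labels, K=meta["K"], voxel_size=tuple(meta["voxel_size_nm_zyx"]),
                  provenance=meta.get("provenance", "real"))


def write_json(obj, path: str | Path) -> None:
    """JSON-serialize dataclasses / numpy containers for provenance files."""
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
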