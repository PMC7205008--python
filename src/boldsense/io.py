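"""NIfTI and table I/O helpers shared by the pipeline and CLI."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VolumeGrid


def save_nifti(path: str | Path, data: np.ndarray, grid: VolumeGrid) -> Path:
    """Write a 3D/4D array as NIfTI-1 with the grid's affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), grid.affine)
    zooms = tuple(grid.voxel_size) + ((1.0,) if data.ndim == 4 else ())
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a NIfTI volume onto a :class:`VolumeGrid` (axis-aligned only)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    grid = VolumeGrid(
        shape=tuple(int(n) for n in data.shape[:3]),
        voxel_size=tuple(float(abs(aff[i, i])) for i in range(3)),
        origin=tuple(float(aff[i, 3]) for i in range(3)),
    )
    return data, grid


def save_table(path: str | Path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
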