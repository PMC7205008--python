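"""Common voxel lattice shared by all volumetric maps.

Every map in the pipeline (segment activity, perfusion, fit coefficients,
group statistics) lives on a :class:`VolumeGrid`: an axis-aligned lattice
defined by its shape in voxels, the physical voxel size in millimetres and
a millimetre origin offset.  Analyses are restricted to a boolean mask;
when two modalities with different coverage are combined, their masks are
intersected into a *junction mask* so that every statistic is computed over
an identical voxel set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GridError


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis (i, j, k).
    voxel_size
        Physical voxel size in mm along each axis; strictly positive.
    origin
        World-space (mm) coordinate of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size) != 3:
            raise GridError("grid shape and voxel size must be 3-dimensional")
        if any(int(n) < 1 for n in self.shape):
            raise GridError(f"all axes need >= 1 voxel, got {self.shape}")
        if any(not np.isfinite(v) or v <= 0 for v in self.voxel_size):
            raise GridError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (diagonal scaling plus origin translation)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def coords_mm(self, ijk: np.ndarray) -> np.ndarray:
        """World-space mm coordinates of voxel indices ``ijk`` (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) mm corners of the field of view (voxel centres)."""
        low = np.asarray(self.origin)
        high = self.coords_mm(np.asarray(self.shape, dtype=float) - 1.0)
        return low, high

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def junction_mask(masks: list[np.ndarray] | tuple[np.ndarray, ...]) -> np.ndarray:
    """Voxel-wise logical AND of coverage masks.

    Restricting to the intersection guarantees that activity and perfusion
    statistics are computed over exactly the same voxels.  A warning is
    issued if the intersection is empty.
    """
    if len(masks) == 0:
        raise GridError("need at least one mask")
    shape = np.asarray(masks[0]).shape
    out = np.ones(shape, dtype=bool)
    for m in masks:
        m = np.asarray(m)
        if m.shape != shape:
            raise GridError(f"mask shape {m.shape} does not match {shape}")
        out &= m.astype(bool)
    if not out.any():
        warnings.warn("junction mask is empty: modalities have no shared coverage")
    return out


def ellipsoid_mask(shape: tuple[int, int, int], margin: float = 0.5) -> np.ndarray:
    """Ellipsoidal 'brain' mask inscribed in the grid, used by simulations."""
    axes = [np.arange(n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    centre = [(n - 1) / 2.0 for n in shape]
    radii = [max((n - 1) / 2.0 - margin, 0.75) for n in shape]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return r2 <= 1.0
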