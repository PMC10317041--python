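"""Cartesian image grids.

All volumes in this package live on an isotropic 3D grid described by a
:class:`GridSpec`.  Axis 0 is the left-right (x) axis; the midsagittal
mirror plane is the central voxel plane of that axis.  Voxel ``i`` along an
axis of length ``n`` sits at the physical coordinate ``(i - (n-1)/2) * dx``
millimetres, so the geometric centre of the field of view is at voxel index
``(n-1)/2`` (a half-integer position on even-sized grids).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Isotropic 3D voxel grid.

    Parameters
    ----------
    shape
        Matrix size per axis, each entry >= 8.
    voxel_size_mm
        Isotropic voxel edge length in millimetres, > 0.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3:
            raise ValueError("GridSpec.shape must have three axes")
        if any(n < 8 for n in shape):
            raise ValueError(f"matrix size must be >= 8 per axis, got {shape}")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", float(self.voxel_size_mm))

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        """Field of view per axis (matrix size times voxel size)."""
        return tuple(n * self.voxel_size_mm for n in self.shape)

    @property
    def center(self) -> tuple[float, float, float]:
        """Voxel-index coordinate of the geometric FOV centre."""
        return tuple((n - 1) / 2.0 for n in self.shape)

    def coords_mm(self, axis: int) -> np.ndarray:
        """Physical voxel-centre coordinates along ``axis`` (mm, centred)."""
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size_mm

    def meshgrid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable physical coordinate arrays for the three axes."""
        return np.meshgrid(
            self.coords_mm(0), self.coords_mm(1), self.coords_mm(2), indexing="ij"
        )

    def affine(self) -> np.ndarray:
        """NIfTI affine placing the FOV centre at the world origin."""
        a = np.diag([self.voxel_size_mm] * 3 + [1.0])
        a[:3, 3] = [-c * self.voxel_size_mm for c in self.center]
        return a

    def is_cubic(self) -> bool:
        return len(set(self.shape)) == 1
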