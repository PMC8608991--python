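"""Volumetric containers and world/voxel geometry.

Conventions used throughout the package:

* World coordinates are RAS millimetres.
* Voxel indices are 0-based.  A voxel with index ``(i, j, k)`` is centred at
  ``affine @ (i, j, k, 1)`` and owns the half-open cube
  ``[centre - h/2, centre + h/2)`` along each axis, where ``h`` is the voxel
  size.  Point-to-voxel assignment therefore uses ``floor(frac + 0.5)`` on
  fractional indices, never banker's rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["LabelVolume", "FieldVolume", "make_affine", "sphere_mask"]


def make_affine(shape, voxel_size: float) -> np.ndarray:
    """Diagonal RAS affine placing world (0, 0, 0) on the centre voxel.

    The origin voxel index is ``shape // 2``, so for the default 1 mm grids
    integer world coordinates coincide with voxel centres.
    """
    shape = np.asarray(shape, dtype=int)
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * float(voxel_size)
    aff[:3, 3] = -float(voxel_size) * (shape // 2)
    return aff


@dataclass
class LabelVolume:
    """A 3-D grid of integer labels (or booleans / floats) with an affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, points) -> np.ndarray:
        """Map world-mm points to fractional voxel indices."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_index(self, points) -> np.ndarray:
        """Integer index of the voxel owning each point (half-open cubes)."""
        frac = self.world_to_voxel(points)
        return np.floor(frac + 0.5).astype(np.int64)

    def inside(self, points) -> np.ndarray:
        idx = self.voxel_index(points)
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)

    def sample(self, points, outside=0) -> np.ndarray:
        """Value of the voxel owning each world point; ``outside`` beyond grid."""
        idx = self.voxel_index(points)
        ok = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        out = np.full(idx.shape[0], outside, dtype=self.data.dtype)
        if ok.any():
            sel = idx[ok]
            out[ok] = self.data[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    # -- derived quantities ----------------------------------------------

    def coords_world(self, mask=None) -> np.ndarray:
        """World coordinates of voxel centres where ``mask`` (default: nonzero)."""
        if mask is None:
            mask = self.data != 0
        ijk = np.argwhere(mask)
        return self.voxel_to_world(ijk)

    def centroid_mm(self) -> np.ndarray:
        pts = self.coords_world()
        if pts.size == 0:
            raise ValueError("centroid of an empty volume is undefined")
        return pts.mean(axis=0)

    def count_nonzero(self) -> int:
        return int(np.count_nonzero(self.data))

    # -- I/O ---------------------------------------------------------------

    def save(self, path) -> None:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        nib.save(nib.Nifti1Image(data, self.affine), str(path))

    @classmethod
    def load(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), np.asarray(img.affine))

    def like(self, data: np.ndarray) -> "LabelVolume":
        """A new volume on this grid holding ``data``."""
        return LabelVolume(data, self.affine.copy())


@dataclass
class FieldVolume(LabelVolume):
    """Scalar electric-field magnitude |E| in V/mm on a voxel lattice."""

    meta: dict = field(default_factory=dict)


def sphere_mask(template: LabelVolume, center_mm, radius_mm: float) -> np.ndarray:
    """Boolean array of voxels whose centre lies within ``radius_mm`` of a point."""
    shape = template.shape
    h = template.voxel_size
    origin = template.affine[:3, 3]
    xs = origin[0] + np.arange(shape[0]) * h[0]
    ys = origin[1] + np.arange(shape[1]) * h[1]
    zs = origin[2] + np.arange(shape[2]) * h[2]
    c = np.asarray(center_mm, dtype=float)
    d2 = (
        (xs - c[0])[:, None, None] ** 2
        + (ys - c[1])[None, :, None] ** 2
        + (zs - c[2])[None, None, :] ** 2
    )
    return d2 <= radius_mm**2
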