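"""3D scalar volumes with voxel-to-world geometry.

A :class:`Volume` is the universal currency of the pipeline: phantom images,
subject images, templates and statistic maps are all volumes on an RAS+ grid
with an invertible 4x4 affine.  NIfTI-1 I/O goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "make_grid_affine"]


def make_grid_affine(shape: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """Axis-aligned RAS+ affine with the grid centred on the world origin."""
    shape = np.asarray(shape, dtype=float)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    affine[:3, 3] = -(shape - 1) / 2.0 * voxel_size_mm
    return affine


@dataclass
class Volume:
    """A 3D scalar image plus its voxel-to-world map (mm, RAS+)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world coordinates in mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_center(self) -> np.ndarray:
        """World coordinate of the grid centre."""
        center_ijk = (np.asarray(self.shape, dtype=float) - 1) / 2.0
        return self.voxel_to_world(center_ijk)

    def world_x_coordinates(self) -> np.ndarray:
        """World x (left-right) coordinate of every voxel, shaped like ``data``."""
        ii = np.arange(self.shape[0], dtype=float)
        x = ii * self.affine[0, 0] + self.affine[0, 3]
        # Axis-aligned grids only; asserted when constructed from this package.
        return np.broadcast_to(x[:, None, None], self.shape)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine))

    @classmethod
    def like(cls, other: "Volume", data: np.ndarray) -> "Volume":
        return cls(np.asarray(data, dtype=np.float64), other.affine.copy())
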