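"""Voxel volume container and NIfTI round-trip helpers.

Volumes are 3D scalar grids with axis order ``(x, y, z)``, 0-based indices,
an identity orientation, and voxel centers at ``index * spacing`` (mm).
Each volume is tagged with the physical kind of its values so that
operations can reject inputs of the wrong unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: Recognised unit tags: SUV (g/mL), linear attenuation (cm^-1),
#: Hounsfield units, integer label maps, and unitless ratio fields.
UNITS = ("suv", "mu", "hu", "label", "ratio")


class GridMismatchError(ValueError):
    """Raised when two volumes or a volume and a mask disagree on the grid."""


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    data
        3D array, axis order ``(x, y, z)``.
    spacing
        Voxel spacing in mm, one value per axis.
    unit
        One of :data:`UNITS`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    unit: str

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing!r}")
        object.__setattr__(self, "spacing", spacing)
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ccm(self) -> float:
        """Volume of a single voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0

    def same_grid(self, other: "VoxelVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def require_same_grid(self, other: "VoxelVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}@{self.spacing} vs {other.shape}@{other.spacing}"
            )

    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise ValueError(f"expected a {unit!r} volume, got {self.unit!r}")

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "VoxelVolume":
        """Return a copy carrying ``data`` (and optionally a new unit tag)."""
        return replace(self, data=np.asarray(data), unit=unit or self.unit)

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis coordinates of voxel centers in mm."""
        return tuple(
            np.arange(n, dtype=float) * s for n, s in zip(self.shape, self.spacing)
        )


def save_nifti(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with a diagonal affine built from the spacing."""
    affine = np.diag([*vol.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_nifti(path: str | Path, unit: str) -> VoxelVolume:
    """Load a NIfTI file as a :class:`VoxelVolume` tagged with ``unit``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(data=data, spacing=spacing, unit=unit)
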