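"""Volume-of-interest construction and SUV extraction.

Spheroid VOIs are defined in world coordinates and rasterised by a
voxel-center inclusion test.  Isocontour VOIs take the 26-connected
component, anchored at the hottest voxel of a search region, of all voxels
at or above a fixed fraction of that maximum.  VOIs are copied between
reconstructions as raw index sets — never re-thresholded on the target
image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import VoxelVolume


@dataclass(frozen=True)
class SpheroidVOI:
    """Axis-aligned ellipsoid in world coordinates (mm)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class VOIMask:
    """A set of voxel indices on a stated grid."""

    indices: np.ndarray  # (k, 3) int array
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    source: str = "manual"  # spheroid | isocontour | manual

    def __post_init__(self) -> None:
        idx = np.atleast_2d(np.asarray(self.indices, dtype=int))
        if idx.size == 0:
            raise ValueError("VOI mask must be non-empty")
        if idx.shape[1] != 3:
            raise ValueError("indices must be (k, 3)")
        if (idx < 0).any() or (idx >= np.asarray(self.shape)).any():
            raise ValueError("VOI indices fall outside the grid")
        object.__setattr__(self, "indices", idx)

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    def matches_grid(self, vol: VoxelVolume) -> bool:
        return tuple(self.shape) == vol.shape and np.allclose(self.spacing, vol.spacing)

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.shape, dtype=bool)
        dense[tuple(self.indices.T)] = True
        return dense


@dataclass(frozen=True)
class Measurement:
    """SUVmax/SUVmean/volume for one unit under one reconstruction."""

    patient_id: str
    unit_id: str
    unit_type: str
    recon: str
    suv_max: float
    suv_mean: float
    volume_ccm: float

    def __post_init__(self) -> None:
        if not self.suv_max >= self.suv_mean:
            raise ValueError("suv_max must be >= suv_mean")
        if self.volume_ccm <= 0:
            raise ValueError("volume must be positive")


def spheroid_voi_mask(grid: VoxelVolume, voi: SpheroidVOI) -> VOIMask:
    """Rasterise a spheroid: a voxel belongs iff its center is inside.

    Raises if no voxel center falls inside the ellipsoid.
    """
    xs, ys, zs = grid.voxel_centers_mm()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    c, a = voi.center_mm, voi.semi_axes_mm
    inside = (
        ((gx - c[0]) / a[0]) ** 2 + ((gy - c[1]) / a[1]) ** 2 + ((gz - c[2]) / a[2]) ** 2
    ) <= 1.0
    if not inside.any():
        raise ValueError("spheroid contains no voxel center")
    return VOIMask(
        indices=np.argwhere(inside),
        shape=grid.shape,
        spacing=grid.spacing,
        source="spheroid",
    )


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def isocontour_voi(
    suv: VoxelVolume,
    search_region: VOIMask,
    fraction: float = 0.41,
) -> VOIMask:
    """Fractional-of-max isocontour VOI within a search region.

    Let ``M`` be the maximum SUV inside the region.  The VOI is the
    26-connected component containing the maximum voxel of all region voxels
    with SUV >= ``fraction * M`` (inclusive), so the maximum voxel is always
    a member.
    """
    suv.require_unit("suv")
    if not search_region.matches_grid(suv):
        raise ValueError("search region grid does not match the volume")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    region = search_region.to_dense()
    vals = np.where(region, suv.data, -np.inf)
    max_idx = np.unravel_index(np.argmax(vals), vals.shape)
    m = vals[max_idx]
    if not np.isfinite(m) or m <= 0:
        raise ValueError("search region has no positive SUV")
    above = region & (suv.data >= fraction * m)
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    component = labels == labels[max_idx]
    return VOIMask(
        indices=np.argwhere(component),
        shape=suv.shape,
        spacing=suv.spacing,
        source="isocontour",
    )


def copy_voi(mask: VOIMask, target: VoxelVolume) -> VOIMask:
    """Carry a VOI onto another volume on the identical grid.

    The index set is preserved verbatim — no re-thresholding on the target.
    """
    if not mask.matches_grid(target):
        raise ValueError("target grid differs from the VOI grid")
    return VOIMask(
        indices=mask.indices.copy(),
        shape=mask.shape,
        spacing=mask.spacing,
        source=mask.source,
    )


def voi_stats(
    suv: VoxelVolume,
    mask: VOIMask,
    *,
    patient_id: str = "",
    unit_id: str = "",
    unit_type: str = "",
    recon: str = "AC",
) -> Measurement:
    """SUVmax, SUVmean and volume (ccm) of a VOI on a volume."""
    suv.require_unit("suv")
    if not mask.matches_grid(suv):
        raise ValueError("mask grid does not match the volume")
    vals = suv.data[tuple(mask.indices.T)]
    suv_max = float(vals.max())
    # pairwise summation can push the mean of a constant region a few ulp
    # above its max; clamp to preserve the max >= mean invariant
    suv_mean = min(float(vals.mean()), suv_max)
    return Measurement(
        patient_id=patient_id,
        unit_id=unit_id,
        unit_type=unit_type,
        recon=recon,
        suv_max=suv_max,
        suv_mean=suv_mean,
        volume_ccm=mask.n_voxels * suv.voxel_volume_ccm,
    )


def suv_from_activity(
    activity: VoxelVolume | np.ndarray,
    weight_kg: float,
    injected_activity_mbq: float,
) -> VoxelVolume | np.ndarray:
    """Body-weight SUV from an activity-concentration volume (kBq/mL).

    ``SUV = C[Bq/mL] * weight[g] / injected[Bq]``, which reduces to
    ``C[kBq/mL] * weight[kg] / injected[MBq]``.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if injected_activity_mbq <= 0:
        raise ValueError("injected activity must be positive")
    scale = weight_kg / injected_activity_mbq
    if isinstance(activity, VoxelVolume):
        if np.any(np.asarray(activity.data) < 0):
            raise ValueError("activity must be non-negative")
        return activity.with_data(np.asarray(activity.data) * scale, unit="suv")
    arr = np.asarray(activity, dtype=float)
    if np.any(arr < 0):
        raise ValueError("activity must be non-negative")
    return arr * scale
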