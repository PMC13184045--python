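"""HU-to-mu conversion, per-organ attenuation extraction, and paired tables.

Covers the attenuation-map side of the analysis: converting CT Hounsfield
volumes to 511 keV linear attenuation coefficients, averaging the coefficient
over label-mask organs, in-filling missing contrast-CT coverage with the
low-dose CT, and tabulating paired per-organ attenuation changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import percent_change
from .volume import GridMismatchError, VoxelVolume


@dataclass(frozen=True)
class HuToMuParams:
    """Bilinear HU -> mu(511 keV) conversion parameters.

    Continuous piecewise-linear: soft-tissue slope below the breakpoint, bone
    slope above, clipped at zero.  Defaults put water (0 HU) at 0.096 cm^-1
    and air (-1000 HU) at 0.
    """

    mu_water_511: float = 0.096
    breakpoint_hu: float = 0.0
    soft_slope: float = 9.6e-5
    bone_slope: float = 5.1e-5

    def __post_init__(self) -> None:
        if self.mu_water_511 <= 0 or self.soft_slope <= 0 or self.bone_slope <= 0:
            raise ValueError("mu_water and slopes must be positive")


@dataclass(frozen=True)
class MuMeasurement:
    """Mean linear attenuation coefficient of one organ, one reconstruction."""

    patient_id: str
    organ: str
    recon: str  # "AC" or "CE"
    mean_mu: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.mean_mu < 0:
            raise ValueError("mean_mu must be >= 0")
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")
        if self.recon not in ("AC", "CE"):
            raise ValueError(f"recon must be 'AC' or 'CE', got {self.recon!r}")


def hu_to_mu(volume: VoxelVolume, params: HuToMuParams | None = None) -> VoxelVolume:
    """Convert an HU volume to a 511 keV attenuation-coefficient volume."""
    params = params or HuToMuParams()
    volume.require_unit("hu")
    hu = np.asarray(volume.data, dtype=float)
    # value at the breakpoint, from the soft-tissue branch (continuity)
    mu_break = params.mu_water_511 + params.soft_slope * params.breakpoint_hu
    soft = params.mu_water_511 + params.soft_slope * hu
    bone = mu_break + params.bone_slope * (hu - params.breakpoint_hu)
    mu = np.where(hu <= params.breakpoint_hu, soft, bone)
    return volume.with_data(np.clip(mu, 0.0, None), unit="mu")


def organ_mean_mu(
    mu_volume: VoxelVolume,
    mask: VoxelVolume,
    label: int,
    *,
    patient_id: str = "",
    organ: str = "",
    recon: str = "AC",
) -> MuMeasurement:
    """Arithmetic mean of mu over voxels carrying ``label`` in ``mask``."""
    mu_volume.require_unit("mu")
    mask.require_unit("label")
    mu_volume.require_same_grid(mask)
    sel = mask.data == label
    count = int(sel.sum())
    if count == 0:
        raise ValueError(f"label {label} not present in mask")
    return MuMeasurement(
        patient_id=patient_id,
        organ=organ,
        recon=recon,
        mean_mu=float(mu_volume.data[sel].mean()),
        voxel_count=count,
    )


def infill_missing_slices(
    ce_volume: VoxelVolume,
    missing: np.ndarray,
    ac_volume: VoxelVolume,
    axis: int = 2,
) -> tuple[VoxelVolume, np.ndarray]:
    """Replace flagged axial slices of the CE volume with AC counterparts.

    Parameters
    ----------
    missing
        Either a 1D boolean array with one flag per slice along ``axis``, or
        a 3D boolean mask in which every flagged slice must be marked in
        full (partial slices are rejected).

    Returns
    -------
    completed, replaced
        The completed CE volume and the 1D per-slice provenance flags.
    """
    ce_volume.require_same_grid(ac_volume)
    if ce_volume.unit != ac_volume.unit:
        raise ValueError("CE and AC volumes must carry the same unit")
    missing = np.asarray(missing, dtype=bool)
    n_slices = ce_volume.shape[axis]
    if missing.ndim == 3:
        if missing.shape != ce_volume.shape:
            raise GridMismatchError("3D slice flags must match the volume shape")
        per_slice = missing.any(axis=tuple(i for i in range(3) if i != axis))
        full = missing.all(axis=tuple(i for i in range(3) if i != axis))
        if np.any(per_slice & ~full):
            raise ValueError("flags mark partial slices; only whole axial slices may be in-filled")
        flags = per_slice
    elif missing.ndim == 1:
        if missing.shape[0] != n_slices:
            raise ValueError(f"expected {n_slices} per-slice flags, got {missing.shape[0]}")
        flags = missing
    else:
        raise ValueError("missing flags must be 1D (per slice) or 3D (full mask)")

    out = np.array(ce_volume.data, copy=True)
    index = [slice(None)] * 3
    for k in np.nonzero(flags)[0]:
        index[axis] = int(k)
        out[tuple(index)] = ac_volume.data[tuple(index)]
    return ce_volume.with_data(out), flags.copy()


def _box_summary(values: np.ndarray) -> dict[str, float]:
    """Median/quartiles plus Tukey whiskers clamped to the data range."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
    }


def mu_change_table(measurements) -> pd.DataFrame:
    """Per-organ paired attenuation summary.

    Parameters
    ----------
    measurements
        Iterable of :class:`MuMeasurement` or a data frame with columns
        ``patient_id, organ, recon, mean_mu``.  Every (patient, organ) pair
        must appear under both reconstructions.

    Returns
    -------
    One row per organ: box-plot statistics of the raw coefficient per
    reconstruction (``ac_*``/``ce_*`` columns), the per-patient percent
    change median, and the count of strict increases.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "patient_id": m.patient_id,
                    "organ": m.organ,
                    "recon": m.recon,
                    "mean_mu": m.mean_mu,
                }
                for m in measurements
            ]
        )
    if df.empty:
        raise ValueError("no measurements supplied")
    wide = df.pivot_table(
        index=["patient_id", "organ"], columns="recon", values="mean_mu", aggfunc="first"
    )
    if "AC" not in wide.columns or "CE" not in wide.columns or wide.isna().any().any():
        raise ValueError("every (patient, organ) must have both AC and CE entries")

    rows = []
    for organ, grp in wide.groupby(level="organ"):
        ac = grp["AC"].to_numpy(float)
        ce = grp["CE"].to_numpy(float)
        changes = np.array([percent_change(a, c) for a, c in zip(ac, ce)])
        row: dict[str, object] = {"organ": organ, "n": len(grp)}
        for recon, vals in (("ac", ac), ("ce", ce)):
            for key, v in _box_summary(vals).items():
                row[f"{recon}_{key}"] = v
        row["median_change_pct"] = float(np.median(changes))
        row["n_increase"] = int((changes > 0).sum())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("organ").reset_index(drop=True)
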