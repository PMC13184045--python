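"""Seeded synthetic cohort and phantom generation.

Two modes are provided:

* **tabular** — :func:`generate_cohort` draws per-patient reference-organ and
  per-lesion values for two reconstructions (``AC`` and ``CE``), where every
  CE value is its AC counterpart times a multiplicative bias factor drawn
  log-normally with a configurable median.  The ground truth of every draw is
  returned alongside the measurement table so downstream extraction can be
  checked for exact recovery.
* **volume** — :func:`generate_phantom` renders one patient of that truth as a
  set of piecewise-constant voxel volumes (SUV and attenuation for both
  reconstructions plus organ/lesion label masks), suitable for exercising the
  VOI and attenuation-map code paths end to end.

An optional physics mode, :func:`lor_bias_field`, derives a voxelwise
multiplicative bias from line integrals of the attenuation difference over
oblique line-of-response directions; it is not used by the default generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


from .volume import GridMismatchError, VoxelVolume

ORGANS = ("aorta", "liver", "muscle", "vertebra_L5")
#: Tissues carrying an SUV bias factor (reference organs plus lesions).
SUV_TISSUES = ORGANS + ("lesion",)

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


def _log_sd_from_quartiles(q1: float, q3: float) -> float:
    """Log-scale SD of the log-normal matching the given quartile ratio."""
    return math.log(q3 / q1) / (2.0 * _Z75)


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient."""

    patient_id: str
    weight_kg: float
    injected_activity_mbq: float
    has_lesions: bool
    n_lesions: int = 0

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be positive")


@dataclass
class GeneratorConfig:
    """Calibration constants and cohort sizes driving synthesis.

    Default medians and quartiles reproduce the published cohort summary:
    a 21-patient restaging cohort with 18 lesion-bearing patients and 66
    lesions, organ attenuation medians per reconstruction, reference and
    lesion SUVmax quartiles, and tissue-specific multiplicative bias medians
    (aorta SUVmax +8.78%, liver +7.86%, lesions +5.80%, aortic attenuation
    +10.40%, per-lesion aorta SUVR ratio 0.9510).
    """

    n_patients: int = 21
    n_with_lesions: int = 18
    total_lesions: int = 66
    seed: int = 0

    # (Q1, median, Q3) of the AC-reconstruction SUVmax per tissue.
    suv_quartiles: dict = field(
        default_factory=lambda: {
            "aorta": (1.88, 2.21, 2.41),
            "liver": (2.60, 2.87, 3.24),
            "lesion": (2.53, 5.68, 12.26),
            "muscle": (0.55, 0.65, 0.80),
            "vertebra_L5": (1.40, 1.70, 2.10),
        }
    )
    # SUVmean as a fraction of SUVmax (applied to both reconstructions).
    suv_mean_fraction: dict = field(
        default_factory=lambda: {
            "aorta": 0.80,
            "liver": 0.81,
            "lesion": 0.65,
            "muscle": 0.80,
            "vertebra_L5": 0.80,
        }
    )
    # Median multiplicative SUV change CE/AC per tissue.
    suv_factor_medians: dict = field(
        default_factory=lambda: {
            "aorta": 1.0878,
            "liver": 1.0786,
            "lesion": 1.0580,
            "muscle": 1.0300,
            "vertebra_L5": 1.0300,
        }
    )
    # Median attenuation coefficient (cm^-1) per organ and reconstruction.
    mu_medians_ac: dict = field(
        default_factory=lambda: {
            "aorta": 0.0992,
            "liver": 0.0998,
            "muscle": 0.0981,
            "vertebra_L5": 0.1215,
        }
    )
    mu_medians_ce: dict = field(
        default_factory=lambda: {
            "aorta": 0.1091,
            "liver": 0.1044,
            "muscle": 0.0988,
            "vertebra_L5": 0.1264,
        }
    )
    # Median multiplicative attenuation change CE/AC per organ.  The aorta
    # value is the published median of per-patient ratios (+10.40%); the
    # others fall back to the ratio of the published medians.
    mu_factor_medians: dict = field(
        default_factory=lambda: {
            "aorta": 1.1040,
            "liver": 1.0461,
            "muscle": 1.0071,
            "vertebra_L5": 1.0403,
        }
    )
    #: Median of the per-lesion aorta-SUVR ratio CE/AC (drives a -4.90%
    #: median per-lesion SUVR change when lesion coupling is "aorta_suvr").
    suvr_aorta_factor_median: float = 0.9510
    #: "aorta_suvr": lesion CE factor = suvr ratio draw x patient aorta
    #: factor, so the per-lesion aorta SUVR change has the configured median.
    #: "independent": lesion CE factor drawn directly with the lesion median.
    lesion_coupling: str = "aorta_suvr"

    factor_log_sd: float = 0.03  # dispersion of all bias-factor draws
    mu_log_sd: float = 0.01  # patient-to-patient spread of baseline mu
    truncate_positive: bool = False

    weight_mean_kg: float = 70.0
    weight_sd_kg: float = 12.0
    dose_mbq_per_kg: float = 3.0

    # Descriptive VOI volumes (ccm); identical for both reconstructions
    # because VOIs are copied, never re-drawn.
    voi_volume_medians_ccm: dict = field(
        default_factory=lambda: {
            "aorta": 3.1,
            "liver": 60.2,
            "muscle": 5.0,
            "vertebra_L5": 15.0,
            "lesion": 2.5,
        }
    )
    voi_volume_log_sd: float = 0.2
    max_lesions_per_patient: int = 12

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.n_with_lesions <= self.n_patients:
            raise ValueError("n_with_lesions must be between 0 and n_patients")
        if self.n_with_lesions == 0:
            if self.total_lesions != 0:
                raise ValueError("total_lesions must be 0 when no patient has lesions")
        elif self.total_lesions < self.n_with_lesions:
            raise ValueError("total_lesions must be >= n_with_lesions")
        if self.total_lesions > self.n_with_lesions * self.max_lesions_per_patient:
            raise ValueError("total_lesions exceeds per-patient capacity")
        if self.lesion_coupling not in ("aorta_suvr", "independent"):
            raise ValueError(f"unknown lesion_coupling {self.lesion_coupling!r}")
        for name, d in (
            ("suv_factor_medians", self.suv_factor_medians),
            ("mu_factor_medians", self.mu_factor_medians),
            ("mu_medians_ac", self.mu_medians_ac),
            ("mu_medians_ce", self.mu_medians_ce),
        ):
            for key, val in d.items():
                if val <= 0:
                    raise ValueError(f"{name}[{key!r}] must be > 0")
        if self.suvr_aorta_factor_median <= 0:
            raise ValueError("suvr_aorta_factor_median must be > 0")
        for tissue, (q1, med, q3) in self.suv_quartiles.items():
            if not 0 < q1 < med < q3:
                raise ValueError(f"suv_quartiles[{tissue!r}] must satisfy 0 < Q1 < median < Q3")
        if self.factor_log_sd < 0 or self.mu_log_sd < 0:
            raise ValueError("dispersions must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth behind a generated cohort.

    ``patients``, ``organs`` and ``lesions`` are data frames holding every
    drawn quantity (baseline values and bias factors), from which each row of
    the emitted measurement table is exactly derivable.
    """

    config: GeneratorConfig
    patients: pd.DataFrame
    organs: pd.DataFrame
    lesions: pd.DataFrame


def _lognormal(rng: np.random.Generator, median: float, log_sd: float, size=None):
    if log_sd == 0:
        return np.full(size, median) if size is not None else float(median)
    return np.exp(rng.normal(math.log(median), log_sd, size=size))


def _truncated_factor(rng: np.random.Generator, median: float, log_sd: float) -> float:
    """One log-normal draw conditioned on being > 1 (rejection sampling)."""
    if log_sd == 0:
        if median <= 1.0:
            raise ValueError("cannot truncate a degenerate factor with median <= 1")
        return float(median)
    for _ in range(10_000):
        f = float(np.exp(rng.normal(math.log(median), log_sd)))
        if f > 1.0:
            return f
    raise RuntimeError("truncated factor sampling failed to converge")


def sample_bias_factor(
    tissue: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    kind: str = "suv",
    size: int | None = None,
):
    """Draw multiplicative CE/AC bias factor(s) for one tissue.

    Factors are log-normal, parameterised by their *median* (the calibration
    constant) and the log-scale SD ``config.factor_log_sd``.  With
    ``config.truncate_positive`` every draw is conditioned on exceeding 1.

    Parameters
    ----------
    tissue
        One of :data:`SUV_TISSUES` for ``kind="suv"``; one of :data:`ORGANS`
        for ``kind="mu"``.
    kind
        ``"suv"`` or ``"mu"`` — selects the median table.
    size
        If given, return an array of independent draws.
    """
    medians = config.suv_factor_medians if kind == "suv" else config.mu_factor_medians
    if tissue not in medians:
        raise KeyError(f"no configured {kind} bias-factor median for tissue {tissue!r}")
    median = medians[tissue]
    if not config.truncate_positive:
        return _lognormal(rng, median, config.factor_log_sd, size=size)
    if size is None:
        return _truncated_factor(rng, median, config.factor_log_sd)
    return np.array(
        [_truncated_factor(rng, median, config.factor_log_sd) for _ in range(size)]
    )


def _allocate_lesions(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Lesion counts per lesion-bearing patient: each gets >= 1, capped."""
    n = config.n_with_lesions
    counts = np.ones(n, dtype=int)
    for _ in range(config.total_lesions - n):
        while True:
            i = int(rng.integers(0, n))
            if counts[i] < config.max_lesions_per_patient:
                counts[i] += 1
                break
    return counts


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTruth, pd.DataFrame]:
    """Generate a cohort and its long-format measurement table.

    Returns
    -------
    truth
        :class:`CohortTruth` with every drawn baseline value and factor.
    measurements
        Data frame with one row per (unit, reconstruction):
        ``patient_id, unit_id, unit_type, recon, suv_max, suv_mean,
        volume_ccm, mu_mean`` (``mu_mean`` is NaN for lesions).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    weights = np.clip(rng.normal(config.weight_mean_kg, config.weight_sd_kg, n), 40.0, 140.0)
    injected = config.dose_mbq_per_kg * weights
    lesion_patient_idx = np.sort(rng.choice(n, size=config.n_with_lesions, replace=False))
    has_lesions = np.zeros(n, dtype=bool)
    has_lesions[lesion_patient_idx] = True
    lesion_counts = (
        _allocate_lesions(config, rng) if config.n_with_lesions else np.zeros(0, dtype=int)
    )
    n_lesions = np.zeros(n, dtype=int)
    n_lesions[lesion_patient_idx] = lesion_counts

    ids = [f"P{i + 1:04d}" for i in range(n)]
    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "weight_kg": weights,
            "injected_activity_mbq": injected,
            "has_lesions": has_lesions,
            "n_lesions": n_lesions,
        }
    )

    organ_rows = []
    aorta_factor_by_patient: dict[str, float] = {}
    for organ in ORGANS:
        q1, med, q3 = config.suv_quartiles[organ]
        log_sd = _log_sd_from_quartiles(q1, q3)
        suv_ac = _lognormal(rng, med, log_sd, size=n)
        f_suv = sample_bias_factor(organ, config, rng, kind="suv", size=n)
        mu_ac = _lognormal(rng, config.mu_medians_ac[organ], config.mu_log_sd, size=n)
        f_mu = sample_bias_factor(organ, config, rng, kind="mu", size=n)
        vol = _lognormal(
            rng, config.voi_volume_medians_ccm[organ], config.voi_volume_log_sd, size=n
        )
        frac = config.suv_mean_fraction[organ]
        for i, pid in enumerate(ids):
            organ_rows.append(
                {
                    "patient_id": pid,
                    "organ": organ,
                    "suv_max_ac": suv_ac[i],
                    "suv_max_ce": suv_ac[i] * f_suv[i],
                    "suv_mean_ac": suv_ac[i] * frac,
                    "suv_mean_ce": suv_ac[i] * frac * f_suv[i],
                    "suv_factor": f_suv[i],
                    "mu_ac": mu_ac[i],
                    "mu_ce": mu_ac[i] * f_mu[i],
                    "mu_factor": f_mu[i],
                    "volume_ccm": vol[i],
                }
            )
            if organ == "aorta":
                aorta_factor_by_patient[pid] = float(f_suv[i])
    organs = pd.DataFrame(organ_rows)

    lesion_rows = []
    q1, med, q3 = config.suv_quartiles["lesion"]
    lesion_log_sd = _log_sd_from_quartiles(q1, q3)
    frac = config.suv_mean_fraction["lesion"]
    for pi, count in zip(lesion_patient_idx, lesion_counts):
        pid = ids[pi]
        for k in range(int(count)):
            suv_ac = _lognormal(rng, med, lesion_log_sd)
            if config.lesion_coupling == "aorta_suvr":
                f_bp = aorta_factor_by_patient[pid]
                if config.truncate_positive:
                    # condition the total lesion factor (ratio x aorta) on > 1
                    for _ in range(10_000):
                        ratio = _lognormal(
                            rng, config.suvr_aorta_factor_median, config.factor_log_sd
                        )
                        if ratio * f_bp > 1.0:
                            break
                    else:
                        raise RuntimeError("lesion factor truncation failed to converge")
                else:
                    ratio = _lognormal(
                        rng, config.suvr_aorta_factor_median, config.factor_log_sd
                    )
                factor = ratio * f_bp
            else:
                ratio = math.nan
                factor = sample_bias_factor("lesion", config, rng, kind="suv")
            vol = _lognormal(
                rng, config.voi_volume_medians_ccm["lesion"], config.voi_volume_log_sd
            )
            lesion_rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": f"{pid}:lesion{k + 1}",
                    "suv_max_ac": suv_ac,
                    "suv_max_ce": suv_ac * factor,
                    "suv_mean_ac": suv_ac * frac,
                    "suv_mean_ce": suv_ac * frac * factor,
                    "suv_factor": factor,
                    "suvr_aorta_ratio": ratio,
                    "volume_ccm": vol,
                }
            )
    lesions = pd.DataFrame(
        lesion_rows,
        columns=[
            "patient_id",
            "lesion_id",
            "suv_max_ac",
            "suv_max_ce",
            "suv_mean_ac",
            "suv_mean_ce",
            "suv_factor",
            "suvr_aorta_ratio",
            "volume_ccm",
        ],
    )

    truth = CohortTruth(config=config, patients=patients, organs=organs, lesions=lesions)
    return truth, measurements_from_truth(truth)


def measurements_from_truth(truth: CohortTruth) -> pd.DataFrame:
    """Flatten a :class:`CohortTruth` into the long measurement table."""
    rows = []
    for _, r in truth.organs.iterrows():
        for recon in ("AC", "CE"):
            s = recon.lower()
            rows.append(
                {
                    "patient_id": r["patient_id"],
                    "unit_id": f"{r['patient_id']}:{r['organ']}",
                    "unit_type": r["organ"],
                    "recon": recon,
                    "suv_max": r[f"suv_max_{s}"],
                    "suv_mean": r[f"suv_mean_{s}"],
                    "volume_ccm": r["volume_ccm"],
                    "mu_mean": r[f"mu_{s}"],
                }
            )
    for _, r in truth.lesions.iterrows():
        for recon in ("AC", "CE"):
            s = recon.lower()
            rows.append(
                {
                    "patient_id": r["patient_id"],
                    "unit_id": r["lesion_id"],
                    "unit_type": "lesion",
                    "recon": recon,
                    "suv_max": r[f"suv_max_{s}"],
                    "suv_mean": r[f"suv_mean_{s}"],
                    "volume_ccm": r["volume_ccm"],
                    "mu_mean": math.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "unit_id",
            "unit_type",
            "recon",
            "suv_max",
            "suv_mean",
            "volume_ccm",
            "mu_mean",
        ],
    )


# ---------------------------------------------------------------------------
# Volume mode: piecewise-constant phantoms
# ---------------------------------------------------------------------------

#: Candidate lesion centers (mm) in the free space of the default geometry.
DEFAULT_LESION_SLOTS = (
    (32.0, 32.0, 32.0),
    (224.0, 32.0, 32.0),
    (32.0, 32.0, 224.0),
    (224.0, 32.0, 224.0),
    (224.0, 224.0, 224.0),
    (32.0, 224.0, 224.0),
    (128.0, 32.0, 64.0),
    (128.0, 32.0, 192.0),
    (128.0, 224.0, 128.0),
    (32.0, 128.0, 32.0),
    (224.0, 128.0, 32.0),
    (80.0, 224.0, 128.0),
)


@dataclass
class PhantomSpec:
    """Geometry of the voxel phantom (all coordinates in mm)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    liver_center: tuple[float, float, float] = (76.0, 80.0, 128.0)
    liver_semi_axes: tuple[float, float, float] = (44.0, 36.0, 40.0)
    aorta_center_xy: tuple[float, float] = (180.0, 72.0)
    aorta_radius: float = 13.0
    aorta_z_range: tuple[float, float] = (16.0, 240.0)
    muscle_box: tuple = ((140.0, 220.0), (150.0, 200.0), (30.0, 90.0))
    vertebra_box: tuple = ((40.0, 90.0), (160.0, 210.0), (30.0, 90.0))
    lesion_slots: tuple = DEFAULT_LESION_SLOTS
    lesion_radius: float = 8.0
    background_suv: float = 0.1
    background_mu: float = 0.096
    noise_sigma: float = 0.0  # additive Gaussian, SUV units

    def validate(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValueError("shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.lesion_radius < min(self.spacing):
            raise ValueError(
                f"lesion radius {self.lesion_radius} mm is below the voxel size "
                f"{min(self.spacing)} mm"
            )
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        for c in self.lesion_slots:
            if any(ci - self.lesion_radius < 0 or ci + self.lesion_radius > e
                   for ci, e in zip(c, extent)):
                raise ValueError(f"lesion slot {c} does not fit inside the grid")


#: Integer labels used in the organ mask.
ORGAN_LABELS = {"aorta": 1, "liver": 2, "muscle": 3, "vertebra_L5": 4}


def _organ_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    xs, ys, zs = (
        np.arange(n, dtype=float) * s for n, s in zip(spec.shape, spec.spacing)
    )
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    lc, la = spec.liver_center, spec.liver_semi_axes
    liver = (
        ((gx - lc[0]) / la[0]) ** 2
        + ((gy - lc[1]) / la[1]) ** 2
        + ((gz - lc[2]) / la[2]) ** 2
    ) <= 1.0
    ax, ay = spec.aorta_center_xy
    aorta = (
        ((gx - ax) ** 2 + (gy - ay) ** 2 <= spec.aorta_radius**2)
        & (gz >= spec.aorta_z_range[0])
        & (gz <= spec.aorta_z_range[1])
    )

    def box(b):
        return (
            (gx >= b[0][0]) & (gx <= b[0][1])
            & (gy >= b[1][0]) & (gy <= b[1][1])
            & (gz >= b[2][0]) & (gz <= b[2][1])
        )

    return {
        "aorta": aorta,
        "liver": liver,
        "muscle": box(spec.muscle_box),
        "vertebra_L5": box(spec.vertebra_box),
    }


def _lesion_mask(spec: PhantomSpec, center: tuple[float, float, float]) -> np.ndarray:
    xs, ys, zs = (
        np.arange(n, dtype=float) * s for n, s in zip(spec.shape, spec.spacing)
    )
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
    return d2 <= spec.lesion_radius**2


def generate_phantom(
    truth: CohortTruth,
    patient_id: str,
    spec: PhantomSpec | None = None,
    seed: int | None = None,
) -> dict[str, VoxelVolume]:
    """Render one patient of a cohort truth as piecewise-constant volumes.

    Returns a dict with keys ``suv_ac, suv_ce, mu_ac, mu_ce, organ_mask,
    lesion_mask``.  Organ masks carry :data:`ORGAN_LABELS`; lesion masks are
    labelled ``1..n_lesions`` in lesion-id order.  With ``spec.noise_sigma``
    set, seeded Gaussian noise is added to the SUV volumes only.
    """
    spec = spec or PhantomSpec()
    spec.validate()

    organ_truth = truth.organs[truth.organs["patient_id"] == patient_id]
    if organ_truth.empty:
        raise KeyError(f"unknown patient {patient_id!r}")
    lesion_truth = truth.lesions[truth.lesions["patient_id"] == patient_id]
    if len(lesion_truth) > len(spec.lesion_slots):
        raise ValueError(
            f"patient {patient_id} has {len(lesion_truth)} lesions but the spec "
            f"provides only {len(spec.lesion_slots)} slots"
        )

    masks = _organ_masks(spec)
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"organ geometry overlap: {a} vs {b}")

    suv_ac = np.full(spec.shape, spec.background_suv)
    suv_ce = np.full(spec.shape, spec.background_suv)
    mu_ac = np.full(spec.shape, spec.background_mu)
    mu_ce = np.full(spec.shape, spec.background_mu)
    organ_mask = np.zeros(spec.shape, dtype=np.int16)
    lesion_mask = np.zeros(spec.shape, dtype=np.int16)

    for _, row in organ_truth.iterrows():
        m = masks[row["organ"]]
        suv_ac[m] = row["suv_max_ac"]
        suv_ce[m] = row["suv_max_ce"]
        mu_ac[m] = row["mu_ac"]
        mu_ce[m] = row["mu_ce"]
        organ_mask[m] = ORGAN_LABELS[row["organ"]]

    occupied = np.zeros(spec.shape, dtype=bool)
    for m in masks.values():
        occupied |= m
    for k, (_, row) in enumerate(lesion_truth.iterrows()):
        m = _lesion_mask(spec, spec.lesion_slots[k])
        if not m.any():
            raise ValueError(f"lesion slot {spec.lesion_slots[k]} covers no voxel")
        if np.any(m & occupied):
            raise ValueError(f"lesion at {spec.lesion_slots[k]} overlaps existing structure")
        suv_ac[m] = row["suv_max_ac"]
        suv_ce[m] = row["suv_max_ce"]
        lesion_mask[m] = k + 1
        occupied |= m

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        suv_ac = suv_ac + rng.normal(0.0, spec.noise_sigma, spec.shape)
        suv_ce = suv_ce + rng.normal(0.0, spec.noise_sigma, spec.shape)

    mk = lambda data, unit: VoxelVolume(data=data, spacing=spec.spacing, unit=unit)
    return {
        "suv_ac": mk(suv_ac, "suv"),
        "suv_ce": mk(suv_ce, "suv"),
        "mu_ac": mk(mu_ac, "mu"),
        "mu_ce": mk(mu_ce, "mu"),
        "organ_mask": mk(organ_mask, "label"),
        "lesion_mask": mk(lesion_mask, "label"),
    }


# ---------------------------------------------------------------------------
# Physics mode: attenuation-difference line integrals
# ---------------------------------------------------------------------------


def lor_directions(acceptance_angle_deg: float, n_directions: int) -> np.ndarray:
    """Deterministic unit directions within the acceptance angle.

    The acceptance angle is measured from the transaxial (xy) plane, so a
    direction has polar elevation ``theta`` with ``|theta| <= angle``.  A
    single direction degenerates to the scanner axis (z), matching the
    axial-line special case.  Multiple directions are spread golden-angle in
    azimuth and uniformly in ``sin(theta)`` over the band.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    if not 0 < acceptance_angle_deg <= 90:
        raise ValueError("acceptance angle must be in (0, 90] degrees")
    if n_directions == 1:
        return np.array([[0.0, 0.0, 1.0]])
    a = math.radians(acceptance_angle_deg)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    u = (np.arange(n_directions) + 0.5) / n_directions
    theta = np.arcsin(u * math.sin(a))
    phi = np.arange(n_directions) * golden
    return np.column_stack(
        [np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi), np.sin(theta)]
    )


def lor_bias_field(
    mu_ac: VoxelVolume,
    mu_ce: VoxelVolume,
    acceptance_angle_deg: float = 52.0,
    n_directions: int = 8,
    step_fraction: float = 0.25,
) -> VoxelVolume:
    """Voxelwise multiplicative bias from attenuation-difference line integrals.

    For each voxel ``v`` and each sampled direction the full line through
    ``v`` is traced and ``exp(integral of (mu_ce - mu_ac) dl)`` accumulated;
    the bias is the mean over directions.  Wherever ``mu_ce >= mu_ac``
    everywhere along the lines, the bias is >= 1.

    Line integrals use nearest-neighbour sampling at a step of
    ``step_fraction * min(spacing)``; voxels own the slab ``[-0.5, +0.5]``
    around their center, so a uniform field over an ``n``-voxel extent
    integrates to ``n * spacing``.
    """
    mu_ac.require_unit("mu")
    mu_ce.require_unit("mu")
    mu_ac.require_same_grid(mu_ce)
    dirs = lor_directions(acceptance_angle_deg, n_directions)

    delta = mu_ce.data - mu_ac.data  # cm^-1
    spacing_cm = np.asarray(mu_ac.spacing) / 10.0
    shape = np.asarray(mu_ac.shape)
    ds = step_fraction * float(spacing_cm.min())
    # a voxel may sit at a grid corner, so trace the full diagonal both ways
    reach = float(np.linalg.norm(shape * spacing_cm)) + ds
    ts = np.arange(-reach, reach + ds, ds)

    idx = np.indices(mu_ac.shape, dtype=float).reshape(3, -1)  # voxel coords
    acc = np.zeros(idx.shape[1])
    for d in dirs:
        step_vox = d / spacing_cm  # voxel-index displacement per cm
        integral = np.zeros(idx.shape[1])
        for t in ts:
            # nearest-neighbour lookup; each voxel owns [-0.5, +0.5) around
            # its center so edge voxels contribute their full extent
            near = np.rint(idx + (t * step_vox)[:, None]).astype(int)
            inside = ((near >= 0) & (near < shape[:, None])).all(axis=0)
            vals = delta[tuple(near[:, inside])]
            integral[inside] += vals
        acc += np.exp(integral * ds)
    bias = (acc / len(dirs)).reshape(mu_ac.shape)
    return VoxelVolume(data=bias, spacing=mu_ac.spacing, unit="ratio")
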