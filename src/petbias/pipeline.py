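"""End-to-end orchestration: simulate -> measure -> stats -> deauville.

The pipeline runs either in *tabular* mode (the generated measurement table
feeds the statistics directly) or in *volume* mode (each patient is rendered
as a voxel phantom and all quantities are re-extracted through the VOI and
attenuation-map code paths).  Outputs are report tables (per-organ
attenuation summary, paired SUV summary, SUV-ratio summary, attenuation/SUV
correlation, and misclassification risk curves) plus a manifest capturing the
seed and full configuration, so identical config + seed reproduces an
identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attenuation import mu_change_table, organ_mean_mu
from .deauville import (
    fit_suvr_regression,
    misclassification_probability,
    risk_curve,
    score_change_table,
    suvr_table,
)
from .stats import correlation, paired_summary, wilcoxon_signed_rank
from .synthetic import (
    ORGAN_LABELS,
    CohortTruth,
    GeneratorConfig,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
)
from .voi import SpheroidVOI, VOIMask, copy_voi, isocontour_voi, spheroid_voi_mask, voi_stats

log = logging.getLogger("petbias")

SCHEMA_VERSION = "1"

SUV_UNIT_TYPES = ("aorta", "liver", "muscle", "vertebra_L5", "lesion")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full configuration of one reproducible run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    volume_mode: bool = False
    seed: int | None = None  # overrides generator.seed when set
    suvr_reference_metric: str = "suv_max"  # denominator: reference SUVmax or SUVmean
    wilcoxon_alternative_increase: str = "greater"
    wilcoxon_alternative_decrease: str = "less"
    risk_alpha: float = 0.05
    risk_grid: tuple[float, float, float] = (0.1, 3.0, 0.02)  # start, stop, step
    risk_interval: str = "prediction"

    def resolved_generator(self) -> GeneratorConfig:
        gen = dataclasses.replace(self.generator)
        if self.seed is not None:
            gen.seed = int(self.seed)
        return gen

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["seed"] = self.resolved_generator().seed
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        ph = d.pop("phantom", {})
        for key in ("risk_grid",):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(generator=GeneratorConfig(**gen), phantom=PhantomSpec(**ph), **d)


@dataclass
class ReportBundle:
    truth: CohortTruth
    measurements: pd.DataFrame
    mu_table: pd.DataFrame
    suv_table: pd.DataFrame
    suvr_summary: pd.DataFrame
    suvr_records: pd.DataFrame
    correlation_table: pd.DataFrame
    risk_curves: pd.DataFrame
    fits: dict
    score_changes: dict
    manifest: dict


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Volume-mode measurement
# ---------------------------------------------------------------------------

_AORTA_VOI_RADIUS_MM = 9.05  # ~3.1 ccm sphere
_LIVER_VOI_RADIUS_MM = 24.3  # ~60.2 ccm sphere


def measure_phantom(
    volumes: dict,
    truth: CohortTruth,
    patient_id: str,
    spec: PhantomSpec,
    isocontour_fraction: float = 0.41,
) -> pd.DataFrame:
    """Extract the measurement rows of one patient from phantom volumes.

    Reference organs are measured with fixed-size spheroid VOIs (aorta,
    liver) or the organ label mask (muscle, vertebra); lesions with
    fractional isocontour VOIs defined on the AC reconstruction and copied,
    unchanged, onto the CE reconstruction.  Attenuation means come from the
    organ mask on both attenuation maps.
    """
    suv_ac, suv_ce = volumes["suv_ac"], volumes["suv_ce"]
    mu_ac, mu_ce = volumes["mu_ac"], volumes["mu_ce"]
    organ_mask, lesion_mask = volumes["organ_mask"], volumes["lesion_mask"]

    mid_z = (spec.shape[2] - 1) * spec.spacing[2] / 2.0
    spheroids = {
        "aorta": SpheroidVOI(
            center_mm=(*spec.aorta_center_xy, mid_z),
            semi_axes_mm=(_AORTA_VOI_RADIUS_MM,) * 3,
        ),
        "liver": SpheroidVOI(
            center_mm=spec.liver_center, semi_axes_mm=(_LIVER_VOI_RADIUS_MM,) * 3
        ),
    }

    rows = []
    for organ, label in ORGAN_LABELS.items():
        if organ in spheroids:
            mask = spheroid_voi_mask(suv_ac, spheroids[organ])
        else:
            mask = VOIMask(
                indices=np.argwhere(organ_mask.data == label),
                shape=suv_ac.shape,
                spacing=suv_ac.spacing,
                source="manual",
            )
        mu_meas = {
            recon: organ_mean_mu(
                vol, organ_mask, label, patient_id=patient_id, organ=organ, recon=recon
            )
            for recon, vol in (("AC", mu_ac), ("CE", mu_ce))
        }
        for recon, vol in (("AC", suv_ac), ("CE", suv_ce)):
            m = voi_stats(
                vol,
                copy_voi(mask, vol),
                patient_id=patient_id,
                unit_id=f"{patient_id}:{organ}",
                unit_type=organ,
                recon=recon,
            )
            rows.append(
                {
                    "patient_id": m.patient_id,
                    "unit_id": m.unit_id,
                    "unit_type": m.unit_type,
                    "recon": recon,
                    "suv_max": m.suv_max,
                    "suv_mean": m.suv_mean,
                    "volume_ccm": m.volume_ccm,
                    "mu_mean": mu_meas[recon].mean_mu,
                }
            )

    lesion_truth = truth.lesions[truth.lesions["patient_id"] == patient_id]
    pad = spec.lesion_radius + 2 * max(spec.spacing)
    for k, (_, lrow) in enumerate(lesion_truth.iterrows()):
        center = spec.lesion_slots[k]
        lo = [max(0, int(np.floor((c - pad) / s))) for c, s in zip(center, spec.spacing)]
        hi = [
            min(n - 1, int(np.ceil((c + pad) / s)))
            for c, s, n in zip(center, spec.spacing, spec.shape)
        ]
        box = np.array(
            [
                (i, j, kk)
                for i in range(lo[0], hi[0] + 1)
                for j in range(lo[1], hi[1] + 1)
                for kk in range(lo[2], hi[2] + 1)
            ]
        )
        search = VOIMask(
            indices=box, shape=suv_ac.shape, spacing=suv_ac.spacing, source="manual"
        )
        voi = isocontour_voi(suv_ac, search, fraction=isocontour_fraction)
        for recon, vol in (("AC", suv_ac), ("CE", suv_ce)):
            m = voi_stats(
                vol,
                copy_voi(voi, vol),
                patient_id=patient_id,
                unit_id=lrow["lesion_id"],
                unit_type="lesion",
                recon=recon,
            )
            rows.append(
                {
                    "patient_id": m.patient_id,
                    "unit_id": m.unit_id,
                    "unit_type": "lesion",
                    "recon": recon,
                    "suv_max": m.suv_max,
                    "suv_mean": m.suv_mean,
                    "volume_ccm": m.volume_ccm,
                    "mu_mean": np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stats stage
# ---------------------------------------------------------------------------


def _paired_values(measurements: pd.DataFrame, unit_type: str, metric: str) -> pd.DataFrame:
    sub = measurements[measurements["unit_type"] == unit_type]
    wide = sub.pivot_table(index="unit_id", columns="recon", values=metric, aggfunc="first")
    if wide.empty or "AC" not in wide.columns or "CE" not in wide.columns:
        raise ValueError(f"no paired {metric} data for {unit_type}")
    if wide.isna().any().any():
        raise ValueError(f"unpaired {metric} entries for {unit_type}")
    return wide


def build_suv_table(measurements: pd.DataFrame, alternative: str = "greater") -> pd.DataFrame:
    """Paired SUV summary per unit type and metric (SUVmax and SUVmean)."""
    rows = []
    for unit_type in SUV_UNIT_TYPES:
        if not (measurements["unit_type"] == unit_type).any():
            continue
        for metric in ("suv_max", "suv_mean"):
            wide = _paired_values(measurements, unit_type, metric)
            summ = paired_summary(zip(wide["AC"], wide["CE"]))
            diffs = (wide["CE"] - wide["AC"]).to_numpy(float)
            wres = wilcoxon_signed_rank(diffs, alternative=alternative)
            row = {"unit_type": unit_type, "metric": metric, "n": summ.n}
            for recon, s in (("ac", summ.ac), ("ce", summ.ce)):
                row.update(
                    {
                        f"{recon}_median": s.median,
                        f"{recon}_mad": s.mad,
                        f"{recon}_iqr": s.iqr,
                        f"{recon}_q1": s.q1,
                        f"{recon}_q3": s.q3,
                    }
                )
            row["n_increase"] = summ.n_increase
            row["frac_increase"] = summ.n_increase / summ.n
            row["median_change_pct"] = summ.median_percent_change
            row["wilcoxon_p"] = wres.pvalue
            row["wilcoxon_method"] = wres.method
            rows.append(row)
    return pd.DataFrame(rows)


def build_mu_table(measurements: pd.DataFrame) -> pd.DataFrame:
    organ_rows = measurements[measurements["unit_type"] != "lesion"]
    df = organ_rows[["patient_id", "unit_type", "recon", "mu_mean"]].rename(
        columns={"unit_type": "organ", "mu_mean": "mean_mu"}
    )
    return mu_change_table(df)


def build_correlation_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Percent attenuation change vs percent SUVmax change, per organ and pooled."""
    organ_rows = measurements[measurements["unit_type"] != "lesion"]
    per_organ: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for organ, grp in organ_rows.groupby("unit_type"):
        mu = grp.pivot_table(index="unit_id", columns="recon", values="mu_mean", aggfunc="first")
        suv = grp.pivot_table(index="unit_id", columns="recon", values="suv_max", aggfunc="first")
        dmu = (100.0 * (mu["CE"] - mu["AC"]) / mu["AC"]).to_numpy(float)
        dsuv = (100.0 * (suv["CE"] - suv["AC"]) / suv["AC"]).to_numpy(float)
        per_organ[organ] = (dmu, dsuv)
    pooled = (
        np.concatenate([v[0] for v in per_organ.values()]),
        np.concatenate([v[1] for v in per_organ.values()]),
    )
    rows = []
    for tissue, (x, y) in [*sorted(per_organ.items()), ("all", pooled)]:
        row: dict[str, object] = {"tissue": tissue, "n": len(x)}
        for method, prefix in (("pearson", "pearson"), ("spearman", "spearman")):
            try:
                res = correlation(x, y, method=method)
                row[f"{prefix}_coef"] = res.coefficient
                row[f"{prefix}_p"] = res.pvalue
            except ValueError:
                row[f"{prefix}_coef"] = np.nan
                row[f"{prefix}_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def build_suvr_summary(
    records: pd.DataFrame, alternative: str = "less"
) -> pd.DataFrame:
    """Paired summary of lesion SUV ratios per reference organ."""
    rows = []
    for reference in ("aorta", "liver"):
        col = f"suvr_{reference}"
        wide = records.pivot_table(index="lesion_id", columns="recon", values=col, aggfunc="first")
        if wide.isna().any().any():
            raise ValueError(f"unpaired SUVR entries for reference {reference}")
        summ = paired_summary(zip(wide["AC"], wide["CE"]))
        diffs = (wide["CE"] - wide["AC"]).to_numpy(float)
        wres = wilcoxon_signed_rank(diffs, alternative=alternative)
        changes = 100.0 * (wide["CE"] - wide["AC"]) / wide["AC"]
        row = {"reference": reference, "n": summ.n}
        for recon, s in (("ac", summ.ac), ("ce", summ.ce)):
            row.update(
                {
                    f"{recon}_median": s.median,
                    f"{recon}_mad": s.mad,
                    f"{recon}_iqr": s.iqr,
                    f"{recon}_q1": s.q1,
                    f"{recon}_q3": s.q3,
                }
            )
        row["n_decrease"] = int((changes < 0).sum())
        row["frac_decrease"] = row["n_decrease"] / summ.n
        row["median_change_pct"] = summ.median_percent_change
        row["wilcoxon_p"] = wres.pvalue
        row["wilcoxon_method"] = wres.method
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage %s: FAILED: %s", name, exc)
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done", name)
            return out

        return wrapper

    return deco


@_stage("simulate")
def _simulate(config: RunConfig):
    return generate_cohort(config.resolved_generator())


@_stage("measure")
def _measure(config: RunConfig, truth: CohortTruth, tabular: pd.DataFrame) -> pd.DataFrame:
    if not config.volume_mode:
        return tabular
    gen = config.resolved_generator()
    frames = []
    for i, pid in enumerate(truth.patients["patient_id"]):
        volumes = generate_phantom(truth, pid, config.phantom, seed=gen.seed * 100_003 + i)
        frames.append(measure_phantom(volumes, truth, pid, config.phantom))
    return pd.concat(frames, ignore_index=True)


@_stage("stats")
def _stats(config: RunConfig, measurements: pd.DataFrame):
    suv = build_suv_table(measurements, alternative=config.wilcoxon_alternative_increase)
    mu = build_mu_table(measurements)
    corr = build_correlation_table(measurements)
    return suv, mu, corr


_EMPTY_SUVR_COLS = ["patient_id", "lesion_id", "recon", "suvr_aorta", "suvr_liver", "score"]


@_stage("deauville")
def _deauville(config: RunConfig, measurements: pd.DataFrame):
    if not (measurements["unit_type"] == "lesion").any():
        log.info("no lesions in cohort; emitting empty lesion-level outputs")
        empty = pd.DataFrame(columns=_EMPTY_SUVR_COLS)
        return (
            empty,
            pd.DataFrame(),
            {},
            pd.DataFrame(columns=["reference", "suvr_ce", "direction", "probability", "risk_flag"]),
            {"crosstab": {}, "changed": [], "n_upgraded": 0, "n_downgraded": 0},
        )
    records = suvr_table(measurements, reference_metric=config.suvr_reference_metric)
    summary = build_suvr_summary(records, alternative=config.wilcoxon_alternative_decrease)
    start, stop, step = config.risk_grid
    grid = np.arange(start, stop + step / 2, step)
    fits: dict[str, dict] = {}
    curves = []
    for reference in ("aorta", "liver"):
        col = f"suvr_{reference}"
        wide = records.pivot_table(index="lesion_id", columns="recon", values=col, aggfunc="first")
        fit = fit_suvr_regression(wide["CE"], wide["AC"])
        eps = 1e-9
        fits[reference] = {
            **fit.to_dict(),
            "interval": config.risk_interval,
            "p_false_upgrade_at_1": misclassification_probability(
                fit, 1.0 + eps, interval=config.risk_interval
            ),
            "p_false_downgrade_at_1": misclassification_probability(
                fit, 1.0 - eps, interval=config.risk_interval
            ),
        }
        curve = risk_curve(fit, grid, interval=config.risk_interval)
        curve.insert(0, "reference", reference)
        curve["risk_flag"] = curve["probability"] > config.risk_alpha
        curves.append(curve)
    changes = score_change_table(records)
    score_changes = {
        "crosstab": {
            str(ac): {str(ce): int(v) for ce, v in row.items()}
            for ac, row in changes.crosstab.iterrows()
        },
        "changed": changes.changed.to_dict(orient="records"),
        "n_upgraded": changes.n_upgraded,
        "n_downgraded": changes.n_downgraded,
    }
    return records, summary, fits, pd.concat(curves, ignore_index=True), score_changes


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Run the full analysis and (optionally) write the report bundle."""
    truth, tabular = _simulate(config)
    measurements = _measure(config, truth, tabular)
    suv_table_df, mu_table_df, corr_table = _stats(config, measurements)
    records, suvr_summary, fits, curves, score_changes = _deauville(config, measurements)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "petbias_version": __version__,
        "seed": config.resolved_generator().seed,
        "config": config.to_dict(),
        "config_sha256": config_hash(config),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": [
            "measurements.csv",
            "mu_table.csv",
            "suv_table.csv",
            "suvr_table.csv",
            "suvr_records.csv",
            "correlation_table.csv",
            "risk_curves.csv",
            "fits.json",
            "score_changes.json",
        ],
    }
    bundle = ReportBundle(
        truth=truth,
        measurements=measurements,
        mu_table=mu_table_df,
        suv_table=suv_table_df,
        suvr_summary=suvr_summary,
        suvr_records=records,
        correlation_table=corr_table,
        risk_curves=curves,
        fits=fits,
        score_changes=score_changes,
        manifest=manifest,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.measurements.to_csv(out / "measurements.csv", index=False)
    bundle.mu_table.to_csv(out / "mu_table.csv", index=False)
    bundle.suv_table.to_csv(out / "suv_table.csv", index=False)
    bundle.suvr_summary.to_csv(out / "suvr_table.csv", index=False)
    bundle.suvr_records.to_csv(out / "suvr_records.csv", index=False)
    bundle.correlation_table.to_csv(out / "correlation_table.csv", index=False)
    bundle.risk_curves.to_csv(out / "risk_curves.csv", index=False)
    (out / "fits.json").write_text(json.dumps(bundle.fits, indent=2, sort_keys=True))
    (out / "score_changes.json").write_text(
        json.dumps(bundle.score_changes, indent=2, sort_keys=True)
    )
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    bundle.truth.patients.to_csv(out / "truth_patients.csv", index=False)
    bundle.truth.organs.to_csv(out / "truth_organs.csv", index=False)
    bundle.truth.lesions.to_csv(out / "truth_lesions.csv", index=False)
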