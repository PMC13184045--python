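"""SUV ratios, rule-based Deauville scoring, and misclassification risk.

A lesion's response class is assigned purely from its SUV ratios to the
blood pool (aorta) and liver: score 2 if the aorta ratio is at most 1,
score 3 if above 1 with the liver ratio at most 1, and score 4 otherwise.
Scores 1 and 5 are never emitted — they require comparison with a prior
examination and are out of scope.

The risk model regresses the low-dose-CT-based ratio (taken as the reference
reading) on the contrast-CT-based ratio by ordinary least squares, treats the
prediction distribution at an observed ratio as Gaussian, and evaluates the
probability that the reference reading falls on the other side of the
score threshold — a false upgrade for observed ratios above the threshold,
a false downgrade below it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


def suvr(lesion_suv: float, reference_suv: float) -> float:
    """Lesion-to-reference SUV ratio."""
    if reference_suv <= 0:
        raise ValueError("reference SUV must be positive")
    return lesion_suv / reference_suv


def deauville_score(suvr_aorta: float, suvr_liver: float) -> int:
    """Rule-based Deauville score in {2, 3, 4}.

    The boundary ratio 1.0 maps to the lower score.  The liver clause takes
    precedence: a liver ratio above 1 yields 4 regardless of the aorta ratio.
    """
    if suvr_aorta <= 0 or suvr_liver <= 0:
        raise ValueError("ratios must be positive")
    if suvr_liver > 1.0:
        return 4
    if suvr_aorta > 1.0:
        return 3
    return 2


@dataclass(frozen=True)
class FitResult:
    """Ordinary-least-squares summary of the AC-on-CE ratio regression."""

    intercept: float
    slope: float
    resid_sd: float  # sqrt(RSS / (n - 2))
    n: int
    x_mean: float
    sxx: float  # predictor sum of squares around its mean

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")
        if self.sxx <= 0:
            raise ValueError("sxx must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def fit_suvr_regression(suvr_ce, suvr_ac) -> FitResult:
    """OLS fit of the AC-based ratio (response) on the CE-based ratio."""
    x = np.asarray(suvr_ce, dtype=float)
    y = np.asarray(suvr_ac, dtype=float)
    if x.size != y.size:
        raise ValueError("predictor and response must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    x_mean = x.mean()
    sxx = float(((x - x_mean) ** 2).sum())
    if sxx == 0:
        raise ValueError("constant predictor")
    slope = float(((x - x_mean) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x_mean)
    resid = y - (intercept + slope * x)
    resid_sd = float(np.sqrt((resid**2).sum() / (n - 2)))
    return FitResult(intercept, slope, resid_sd, int(n), float(x_mean), sxx)


def prediction_distribution(
    fit: FitResult, r: float, interval: str = "prediction"
) -> tuple[float, float]:
    """Gaussian (mean, sd) of the reference-reading ratio at observed ``r``.

    ``interval="prediction"`` includes the residual term (new-observation
    spread); ``"confidence"`` covers only the fitted-mean uncertainty.
    """
    if interval not in ("prediction", "confidence"):
        raise ValueError(f"unknown interval kind {interval!r}")
    mean = fit.intercept + fit.slope * r
    base = 1.0 if interval == "prediction" else 0.0
    sd = fit.resid_sd * np.sqrt(base + 1.0 / fit.n + (r - fit.x_mean) ** 2 / fit.sxx)
    return float(mean), float(sd)


def misclassification_probability(
    fit: FitResult,
    r: float,
    threshold: float = 1.0,
    interval: str = "prediction",
) -> float:
    """Probability that the reference reading crosses the score threshold.

    For an observed ratio above the threshold this is the false-upgrade
    probability ``P(reference <= threshold)``; below the threshold it is the
    false-downgrade probability ``P(reference > threshold)``.
    """
    if r == threshold:
        raise ValueError("misclassification is undefined exactly at the threshold")
    mean, sd = prediction_distribution(fit, r, interval=interval)
    if sd == 0:
        if mean == threshold:
            raise ValueError("degenerate fit: zero spread with mean at the threshold")
        if r > threshold:
            return 1.0 if mean <= threshold else 0.0
        return 1.0 if mean > threshold else 0.0
    if r > threshold:
        return float(norm.cdf(threshold, loc=mean, scale=sd))
    return float(norm.sf(threshold, loc=mean, scale=sd))


def risk_flag(fit: FitResult, r: float, alpha: float = 0.05, threshold: float = 1.0) -> bool:
    """True when the misclassification probability exceeds ``alpha``."""
    return misclassification_probability(fit, r, threshold=threshold) > alpha


def risk_curve(
    fit: FitResult,
    grid,
    threshold: float = 1.0,
    interval: str = "prediction",
) -> pd.DataFrame:
    """Misclassification probability over a grid of observed ratios.

    Grid points equal to the threshold are skipped.  Returns columns
    ``suvr_ce, direction, probability``.
    """
    rows = []
    for r in np.asarray(grid, dtype=float):
        if r == threshold:
            continue
        rows.append(
            {
                "suvr_ce": float(r),
                "direction": "upgrade" if r > threshold else "downgrade",
                "probability": misclassification_probability(
                    fit, float(r), threshold=threshold, interval=interval
                ),
            }
        )
    return pd.DataFrame(rows)


def suvr_table(
    measurements: pd.DataFrame,
    reference_metric: str = "suv_max",
    lesion_metric: str = "suv_max",
) -> pd.DataFrame:
    """Per-lesion SUV ratios and scores for both reconstructions.

    ``measurements`` is the long measurement table (columns ``patient_id,
    unit_id, unit_type, recon, suv_max, suv_mean``).  The reference
    denominator is the patient's aorta/liver ``reference_metric`` value of
    the *same* reconstruction.  Returns one row per lesion and recon with
    ``suvr_aorta, suvr_liver, score``.
    """
    if reference_metric not in ("suv_max", "suv_mean"):
        raise ValueError("reference_metric must be 'suv_max' or 'suv_mean'")
    refs = (
        measurements[measurements["unit_type"].isin(["aorta", "liver"])]
        .pivot_table(
            index=["patient_id", "recon"],
            columns="unit_type",
            values=reference_metric,
            aggfunc="first",
        )
        .rename(columns={"aorta": "ref_aorta", "liver": "ref_liver"})
    )
    lesions = measurements[measurements["unit_type"] == "lesion"]
    rows = []
    for _, r in lesions.iterrows():
        try:
            ref = refs.loc[(r["patient_id"], r["recon"])]
        except KeyError as exc:
            raise ValueError(
                f"missing reference measurements for patient {r['patient_id']}"
            ) from exc
        sa = suvr(r[lesion_metric], ref["ref_aorta"])
        sl = suvr(r[lesion_metric], ref["ref_liver"])
        rows.append(
            {
                "patient_id": r["patient_id"],
                "lesion_id": r["unit_id"],
                "recon": r["recon"],
                "suvr_aorta": sa,
                "suvr_liver": sl,
                "score": deauville_score(sa, sl),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScoreChanges:
    """Cross-tabulation of per-lesion scores between reconstructions."""

    crosstab: pd.DataFrame  # rows: AC score, columns: CE score
    changed: pd.DataFrame  # lesion_id, score_ac, score_ce
    n_upgraded: int  # CE score above AC score
    n_downgraded: int


def score_change_table(suvr_records: pd.DataFrame) -> ScoreChanges:
    """Compare per-lesion scores between reconstructions.

    ``suvr_records`` must hold both reconstructions for every lesion (as
    produced by :func:`suvr_table`).
    """
    wide = suvr_records.pivot_table(
        index="lesion_id", columns="recon", values="score", aggfunc="first"
    )
    if "AC" not in wide.columns or "CE" not in wide.columns or wide.isna().any().any():
        raise ValueError("every lesion needs a score under both reconstructions")
    wide = wide.astype(int)
    crosstab = pd.crosstab(wide["AC"], wide["CE"])
    changed = (
        wide[wide["AC"] != wide["CE"]]
        .reset_index()
        .rename(columns={"AC": "score_ac", "CE": "score_ce"})
    )
    return ScoreChanges(
        crosstab=crosstab,
        changed=changed,
        n_upgraded=int((wide["CE"] > wide["AC"]).sum()),
        n_downgraded=int((wide["CE"] < wide["AC"]).sum()),
    )
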