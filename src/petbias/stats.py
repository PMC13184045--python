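"""Paired cohort statistics.

Percent changes, robust distribution summaries with box-plot whiskers, the
Wilcoxon signed-rank test (exact enumeration and normal approximation),
Pearson/Spearman correlation, and histogram + kernel-density curves.

The exact Wilcoxon p-value is computed from the full null distribution of the
positive-rank sum (equivalent to enumerating all ``2^n`` sign assignments),
so the one-sided floor at ``n`` untied positive differences is exactly
``2^-n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def percent_change(value_ac: float, value_ce: float) -> float:
    """Percent change ``100 * (CE - AC) / AC``; the baseline must be > 0.

    Note this is not antisymmetric: ``percent_change(a, b)`` generally
    differs from ``-percent_change(b, a)`` because the baselines differ.
    """
    if value_ac <= 0:
        raise ValueError("baseline (AC) value must be positive")
    return 100.0 * (value_ce - value_ac) / value_ac


@dataclass(frozen=True)
class PairedRecord:
    """One paired measurement with its derived percent change."""

    unit_id: str
    value_ac: float
    value_ce: float

    @property
    def percent_change(self) -> float:
        return percent_change(self.value_ac, self.value_ce)


@dataclass(frozen=True)
class DistributionSummary:
    median: float
    mad: float
    iqr: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int


@dataclass(frozen=True)
class PairedSummary:
    """Per-reconstruction summaries plus the paired-change summary."""

    ac: DistributionSummary
    ce: DistributionSummary
    change: DistributionSummary  # summary of the percent changes
    n: int
    n_increase: int  # strictly positive changes
    median_percent_change: float


def mad(values, scale: float = 1.0) -> float:
    """Median absolute deviation, unscaled by default.

    Pass ``scale=1.4826`` for the normal-consistency convention.
    """
    values = np.asarray(values, dtype=float)
    return float(np.median(np.abs(values - np.median(values))) * scale)


def summarize(values, mad_scale: float = 1.0) -> DistributionSummary:
    """Median/MAD/quartile summary with Tukey whiskers clamped to the data.

    Quartiles use linear interpolation of order statistics.  Whiskers sit at
    the most extreme data points inside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    return DistributionSummary(
        median=float(med),
        mad=mad(values, mad_scale),
        iqr=float(iqr),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(values[values >= q1 - 1.5 * iqr].min()),
        whisker_high=float(values[values <= q3 + 1.5 * iqr].max()),
        n=int(values.size),
    )


def paired_summary(records, mad_scale: float = 1.0) -> PairedSummary:
    """Summarise paired AC/CE values and their percent changes.

    ``records`` is an iterable of :class:`PairedRecord` or ``(ac, ce)``
    pairs.
    """
    pairs = [
        (r.value_ac, r.value_ce) if isinstance(r, PairedRecord) else (r[0], r[1])
        for r in records
    ]
    if not pairs:
        raise ValueError("empty input")
    ac = np.array([p[0] for p in pairs], dtype=float)
    ce = np.array([p[1] for p in pairs], dtype=float)
    changes = np.array([percent_change(a, c) for a, c in zip(ac, ce)])
    return PairedSummary(
        ac=summarize(ac, mad_scale),
        ce=summarize(ce, mad_scale),
        change=summarize(changes, mad_scale),
        n=len(pairs),
        n_increase=int((changes > 0).sum()),
        median_percent_change=float(np.median(changes)),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # positive-rank sum W+
    pvalue: float
    n_used: int  # pairs remaining after dropping zero differences
    method: str


def _signed_rank_counts(n: int) -> np.ndarray:
    """Null distribution of W+ for ranks 1..n: counts[w] sign assignments.

    Built by polynomial convolution; equivalent to enumerating the 2^n sign
    patterns.  Counts fit exactly in float64 for the n used here.
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        nxt = counts.copy()
        nxt[r:] += counts[:-r]
        counts = nxt
    return counts


def wilcoxon_signed_rank(
    differences,
    alternative: str = "greater",
    method: str = "auto",
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (classical treatment).  The
    exact method requires untied absolute differences and computes the
    p-value from the full sign-assignment null distribution; the normal
    method applies a tie-corrected, continuity-corrected Gaussian
    approximation.  ``method="auto"`` picks exact when there are no ties and
    ``n <= 50``.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    absd = np.abs(d)
    has_ties = np.unique(absd).size != n
    if method == "auto":
        method = "normal" if (has_ties or n > 50) else "exact"
    if method == "exact" and has_ties:
        raise ValueError("exact method requires untied absolute differences")

    ranks = sps.rankdata(absd)  # average ranks (integers when no ties)
    w_plus = float(ranks[d > 0].sum())

    if method == "exact":
        counts = _signed_rank_counts(n)
        total = 2.0**n
        w = int(round(w_plus))
        p_ge = counts[w:].sum() / total
        p_le = counts[: w + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(w_plus, float(p), n, "exact")

    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    mean = n * (n + 1) / 4.0
    tie_sum = 0.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_sum = float(((tie_counts**3) - tie_counts).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_sum / 48.0
    sd = np.sqrt(var)
    if sd == 0:
        raise ValueError("degenerate variance (all ranks tied)")
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        cc = 0.5 * np.sign(w_plus - mean)
        z = (w_plus - mean - cc) / sd
        p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w_plus, float(min(p, 1.0)), n, "normal")


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    pvalue: float
    method: str
    n: int


def correlation(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r.statistic), float(r.pvalue), method, int(x.size))


# ---------------------------------------------------------------------------
# Histograms and densities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionCurves:
    bin_edges: np.ndarray
    counts: np.ndarray
    grid: np.ndarray | None
    density: np.ndarray | None


def distribution_curves(
    values,
    bins: int | str = "auto",
    n_grid: int = 512,
) -> DistributionCurves:
    """Fixed-width histogram plus a Silverman-bandwidth Gaussian KDE.

    The density is evaluated on a grid extended three bandwidths beyond the
    data range so that it integrates to 1 within ~1%.  For constant samples
    (zero variance) only the histogram is returned.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    counts, edges = np.histogram(values, bins=bins)
    if values.size < 2 or np.ptp(values) == 0:
        return DistributionCurves(edges, counts, None, None)
    kde = sps.gaussian_kde(values, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, n_grid)
    return DistributionCurves(edges, counts, grid, kde(grid))
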