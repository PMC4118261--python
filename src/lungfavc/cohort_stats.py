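"""Summary and test-retest repeatability statistics for cohort measurements.

Per-subject measurements (space volume, air volume, mean FAVC, c/p ratio
per lung and visit) are summarised by mean, sample standard deviation and
coefficient of variation (COV).  Intra-subject repeatability between two
visits is expressed as the standard error of the estimate (SEE) of the
linear regression of visit 2 on visit 1, as a percentage of the grand
mean — the random component of test-retest variability, with any
systematic visit offset absorbed by the regression intercept.  Systematic
differences use the paired t-test, associations the Pearson correlation,
and comparisons between variabilities the variance-ratio F-test.

A reference subject-characteristics table (11 healthy adult male
never-smokers: height, weight, FEV1 and helium-dilution FRC) ships with
the package and is loaded by :func:`load_reference_subjects`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COHORT_COLUMNS",
    "SummaryRow",
    "load_reference_subjects",
    "mean_sd_cov",
    "repeatability_cov",
    "paired_t",
    "pearson_r",
    "f_test_cov",
    "bland_altman",
    "summarize_cohort",
]

#: Required columns of a cohort table; covariates may be absent/blank.
COHORT_COLUMNS = ["subject", "visit", "lung", "space_ml", "air_ml", "favc", "cp"]


class StatsError(ValueError):
    """Degenerate statistical input."""


@dataclass(frozen=True)
class SummaryRow:
    """Mean, sample SD, COV and (optional) repeatability COV, as percents."""

    mean: float
    sd: float
    cov_percent: float
    repeatability_cov_percent: float | None = None


def load_reference_subjects() -> pd.DataFrame:
    """Load the packaged reference cohort characteristics table."""
    with resources.files("lungfavc.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def mean_sd_cov(values) -> SummaryRow:
    """Mean, sample (n-1) standard deviation and COV = 100 * sd / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError(f"need at least 2 values, got {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0:
        raise StatsError("COV undefined for zero mean")
    return SummaryRow(mean, sd, 100.0 * sd / mean)


def repeatability_cov(visit1, visit2) -> float:
    """Test-retest COV: regression SEE as a percent of the grand mean.

    Ordinary least squares of visit 2 on visit 1;
    SEE = sqrt(sum of squared residuals / (n - 2)).  A constant offset
    between visits is absorbed by the intercept and yields 0.
    """
    x = np.asarray(visit1, dtype=float)
    y = np.asarray(visit2, dtype=float)
    if x.size != y.size:
        raise StatsError("visit lists must be paired")
    n = x.size
    if n < 3:
        raise StatsError(f"need at least 3 pairs, got {n}")
    grand_mean = float(np.concatenate([x, y]).mean())
    if grand_mean == 0:
        raise StatsError("repeatability COV undefined for zero grand mean")
    if np.ptp(x) == 0:  # degenerate regressor: intercept-only fit
        resid = y - y.mean()
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
    see = float(np.sqrt((resid**2).sum() / (n - 2)))
    return 100.0 * see / grand_mean


def paired_t(values1, values2) -> tuple[float, float]:
    """Paired t-test on the differences; returns (t, two-sided p)."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.size != y.size or x.size < 2:
        raise StatsError("need paired lists with n >= 2")
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        raise StatsError("zero-variance nonzero differences; t undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise StatsError("need n >= 3 for a correlation")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def f_test_cov(values_a, values_b) -> tuple[float, float]:
    """Variance-ratio F-test between two samples.

    F is the larger sample variance over the smaller, with matching
    degrees of freedom; the two-sided p doubles the upper-tail
    probability.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("need n >= 2 in both samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if min(va, vb) == 0:
        raise StatsError("zero variance in denominator sample")
    if va >= vb:
        f, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = 2.0 * stats.f.sf(f, dfn, dfd)
    return float(f), float(min(p, 1.0))


def bland_altman(pairs) -> dict:
    """Bland-Altman agreement analysis of paired measurements.

    Returns per-pair means ``(v1+v2)/2`` and differences ``v1-v2``, the
    bias (mean difference) and the 95% limits of agreement
    ``bias +/- 1.96 sd(differences)``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise StatsError("need at least 2 (v1, v2) pairs")
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return {
        "means": means,
        "differences": diffs,
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }


def averaged_cov(cov_right: float, cov_left: float) -> float:
    """Simple two-value mean of per-lung COVs (a reporting convenience)."""
    return 0.5 * (cov_right + cov_left)


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Per-lung summary of a cohort table (one row per lung x parameter).

    ``table`` must hold the columns of :data:`COHORT_COLUMNS` with at
    most one row per (subject, visit, lung).  Mean/SD/COV are computed on
    visit-1 values; the repeatability COV is added where both visits are
    present for all subjects.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise StatsError(f"cohort table missing columns {missing}")
    if table.duplicated(["subject", "visit", "lung"]).any():
        raise StatsError("duplicate (subject, visit, lung) rows")
    rows = []
    for lung in ("right", "left"):
        sub = table[table["lung"] == lung]
        v1 = sub[sub["visit"] == 1].sort_values("subject")
        v2 = sub[sub["visit"] == 2].sort_values("subject")
        paired = len(v2) == len(v1) and len(v1) >= 3 and (
            v1["subject"].tolist() == v2["subject"].tolist()
        )
        for param in ("space_ml", "air_ml", "favc", "cp"):
            if len(v1) >= 2:
                s = mean_sd_cov(v1[param])
            else:  # single subject: dispersion undefined
                s = SummaryRow(float(v1[param].iloc[0]), np.nan, np.nan)
            rep = (
                repeatability_cov(v1[param], v2[param]) if paired else None
            )
            rows.append({
                "lung": lung,
                "parameter": param,
                "mean": s.mean,
                "sd": s.sd,
                "cov_percent": s.cov_percent,
                "repeatability_cov_percent": rep,
            })
    return pd.DataFrame(rows)
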