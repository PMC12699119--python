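"""Rater agreement and validity statistics.

Intraclass correlations use the two-way (subjects x raters) single-measure
forms, derived from the ANOVA mean squares of the ratings matrix:

    MS_R  between-subject mean square
    MS_C  between-rater mean square
    MS_E  residual mean square

    ICC(consistency)        = (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    ICC(absolute agreement) = (MS_R - MS_E) /
                              (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

Consistency ignores systematic rater offsets (appropriate within one
observer over occasions); absolute agreement penalizes them (appropriate
between two observers).  Confidence intervals use the standard
F-distribution constructions for these forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .psychometrics import DegenerateDataError

__all__ = [
    "ReliabilityReport",
    "icc",
    "icc_band",
    "spearman_validity",
    "kendall_tau_c",
]

#: Qualitative interpretation bands for ICC point estimates.
_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"))


def icc_band(value: float) -> str:
    """Qualitative band: <0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good,
    >0.90 excellent."""
    for cut, label in _BANDS:
        if value < cut:
            return label
    if value <= 0.90:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ReliabilityReport:
    """Two-way single-measure ICC with its CI and qualitative band."""

    estimate: float
    definition: str  # "consistency" | "absolute-agreement"
    model: str
    ci_low: float
    ci_high: float
    ci_level: float
    band: str
    n_subjects: int
    k_raters: int
    ms_rows: float
    ms_cols: float
    ms_error: float


def _mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def icc(
    ratings: pd.DataFrame | np.ndarray,
    definition: str = "consistency",
    ci_level: float = 0.95,
) -> ReliabilityReport:
    """Two-way single-measure intraclass correlation of a ratings matrix.

    Rows are subjects, columns raters (or occasions); no missing cells.
    ``definition`` selects consistency or absolute agreement.
    """
    if definition not in ("consistency", "absolute-agreement"):
        raise ValueError(f"unknown ICC definition {definition!r}")
    values = np.asarray(ratings, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2 or values.shape[0] < 3:
        raise DegenerateDataError("ratings matrix needs >=3 subjects and >=2 raters")
    if np.isnan(values).any():
        raise DegenerateDataError("ratings matrix has missing cells")
    n, k = values.shape
    ms_rows, ms_cols, ms_err = _mean_squares(values)
    if ms_rows == 0 and ms_err == 0:
        raise DegenerateDataError(
            "no between-subject variance; ICC undefined"
        )

    alpha = 1 - ci_level
    if definition == "consistency":
        if ms_rows + (k - 1) * ms_err == 0:
            raise DegenerateDataError("degenerate mean squares; ICC undefined")
        est = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        if ms_err == 0:
            lo = hi = est
        else:
            fobs = ms_rows / ms_err
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    else:
        denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        if denom == 0:
            raise DegenerateDataError("degenerate mean squares; ICC undefined")
        est = (ms_rows - ms_err) / denom
        if ms_err == 0 and ms_cols == 0:
            lo = hi = est
        else:
            # McGraw & Wong (1996) CI for ICC(A,1)
            a = k * est / (n * (1 - est)) if est < 1 else np.inf
            b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
            v_num = (a * ms_cols + b * ms_err) ** 2
            v_den = (a * ms_cols) ** 2 / (k - 1) + (b * ms_err) ** 2 / (
                (n - 1) * (k - 1)
            )
            v = v_num / v_den if np.isfinite(a) else np.inf
            f_star_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_star_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (
                n * (ms_rows - f_star_u * ms_err)
                / (
                    f_star_u * (k * ms_cols + (k * n - k - n) * ms_err)
                    + n * ms_rows
                )
            )
            hi = (
                n * (f_star_l * ms_rows - ms_err)
                / (
                    k * ms_cols
                    + (k * n - k - n) * ms_err
                    + n * f_star_l * ms_rows
                )
            )
    est = float(est)
    return ReliabilityReport(
        estimate=est,
        definition=definition,
        model="two-way, single measures",
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        band=icc_band(est),
        n_subjects=n,
        k_raters=k,
        ms_rows=float(ms_rows),
        ms_cols=float(ms_cols),
        ms_error=float(ms_err),
    )


def spearman_validity(global_qol, hrqol) -> tuple[float, float]:
    """Spearman rank correlation between owner-rated global QoL (1-5) and
    the computed HRQoL score (face validity of the instrument).

    Ties receive average ranks; the p-value is two-sided.  A constant input
    yields (nan, nan) with a warning.
    """
    x = np.asarray(global_qol, dtype=float)
    y = np.asarray(hrqol, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("inputs must be equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kendall_tau_c(ratings_a, ratings_b) -> tuple[float, float]:
    """Stuart's tau-c ordinal association between two groups' ratings.

    The two samples are stacked into a (group x rating) contingency layout
    and Stuart's tau-c — suited to rectangular tables — is computed with its
    asymptotic two-sided p-value.  If both groups share a single rating
    category the association is zero by convention (with a warning).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    values = np.concatenate([a, b])
    if np.unique(values).size < 2:
        warnings.warn(
            "single shared rating category: tau-c is 0 by convention",
            stacklevel=2,
        )
        return (0.0, float("nan"))
    group = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    res = stats.kendalltau(group, values, variant="c")
    return float(res.statistic), float(res.pvalue)
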