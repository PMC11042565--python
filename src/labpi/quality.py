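"""Data-quality screening for serial results before a personalized
reference interval is computed: Dixon's Q outlier test and an
ordinary-least-squares trend test.

A prediction interval assumes the series comes from a stable process, so
the series is first screened for a single gross outlier (Dixon's Q, the
gap-to-range ratio) and for a systematic drift over time (OLS slope of
value on occasion index).  Screening reports; it never alters the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import MeasurementSeries

__all__ = ["QualityReport", "dixon_q", "trend_test", "assess_quality",
           "DIXON_Q_CRITICAL_95"]

# Two-tailed 95% critical values for Dixon's r10 ratio (gap/range),
# n = 3..30 (Rorabacher's recalculated table).
DIXON_Q_CRITICAL_95: dict[int, float] = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526,
    9: 0.493, 10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396,
    15: 0.384, 16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342,
    21: 0.337, 22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312,
    27: 0.308, 28: 0.305, 29: 0.301, 30: 0.298,
}


@dataclass(frozen=True)
class QualityReport:
    """Outcome of outlier and trend screening on one series."""

    outlier_index: int | None  # index into series.values, or None
    q_statistic: float
    q_critical: float
    trend_slope: float
    trend_p: float
    alpha: float

    @property
    def passed(self) -> bool:
        """True iff no outlier was flagged and the trend is not
        significant."""
        return self.outlier_index is None and self.trend_p > self.alpha


def dixon_q(
    series: MeasurementSeries, alpha: float = 0.05
) -> tuple[float, float, int | None]:
    """Dixon's Q (r10) test for a single outlier in a small sample.

    Q = gap/range for the more extreme of the smallest and largest value;
    the suspect is flagged when Q exceeds the critical value.  Returns
    ``(q_statistic, q_critical, outlier_index_or_None)``.

    Limited to 3 <= n <= 30 by the critical-value table, and to
    ``alpha = 0.05`` (the tabulated level).
    """
    if alpha != 0.05:
        raise ValueError("only alpha = 0.05 is tabulated for Dixon's Q")
    n = len(series)
    if n not in DIXON_Q_CRITICAL_95:
        raise ValueError(f"Dixon's Q requires 3 <= n <= 30, got n = {n}")
    values = np.asarray(series.values)
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    value_range = float(sorted_vals[-1] - sorted_vals[0])
    if value_range == 0:
        raise ValueError("Dixon's Q is undefined for a zero-range series")
    gap_low = float(sorted_vals[1] - sorted_vals[0])
    gap_high = float(sorted_vals[-1] - sorted_vals[-2])
    if gap_high >= gap_low:
        q = gap_high / value_range
        suspect = int(order[-1])
    else:
        q = gap_low / value_range
        suspect = int(order[0])
    q_critical = DIXON_Q_CRITICAL_95[n]
    outlier = suspect if q > q_critical else None
    return q, q_critical, outlier


def trend_test(
    series: MeasurementSeries, alpha: float = 0.05
) -> tuple[float, float]:
    """OLS slope of value on occasion index with a two-sided test of zero
    slope (t, n−2 df).  Returns ``(slope, p_value)``."""
    n = len(series)
    if n < 3:
        raise ValueError("trend test needs at least three results")
    result = stats.linregress(series.time_index, series.values)
    return float(result.slope), float(result.pvalue)


def assess_quality(
    series: MeasurementSeries, alpha: float = 0.05
) -> QualityReport:
    """Run both screens and combine them into a :class:`QualityReport`.

    The series is never modified; how to handle a flagged outlier or a
    significant trend is the caller's decision.
    """
    q, q_crit, outlier = dixon_q(series, alpha=alpha)
    slope, p = trend_test(series, alpha=alpha)
    return QualityReport(
        outlier_index=outlier,
        q_statistic=q,
        q_critical=q_crit,
        trend_slope=slope,
        trend_p=p,
        alpha=alpha,
    )
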