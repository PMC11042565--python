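"""Personalized reference intervals (prRI) and reference change values
(RCV) for monitoring an individual's serial results.

A prRI is a prediction interval centered on the individual's homeostatic
set point.  With few results (3–4) the dispersion is borrowed from the
population within-subject biological variation CV_I (scenario 2, z
multiplier); with five or more results the individual's own mean and SD
are used (scenario 4, t multiplier), after the series passes quality
screening.

The RCV is the smallest percentage difference between two consecutive
results that exceeds combined analytical and biological variation:

* conventional:   RCV   = z·√2·√(CV_A² + CV_I²)      (population CVs)
* personalized:   RCV_P = t(n−1)·√2·CV_P  (or CV_T)  (the individual's CV)

The observed change Δ% = 100·(x1 − x2)/x1 is significant when |Δ| exceeds
the applicable RCV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .intervals import (
    IntervalResult,
    pi_scenario2,
    pi_scenario4,
    summarize,
    t_quantile,
    z_quantile,
)
from .quality import assess_quality
from .series import MeasurementSeries

__all__ = [
    "ChangeAssessment",
    "compute_prri",
    "rcv_conventional",
    "rcv_personalized",
    "delta_percent",
    "evaluate_change",
]

ROUNDING_MODES = ("full_precision", "worked_example")
#: Minimum series length for an own-data prRI.
MIN_N_OWN_DATA = 5
#: Minimum series length for a CV_I-based prRI.
MIN_N_CVI = 3


@dataclass(frozen=True)
class ChangeAssessment:
    """Verdict on the difference between two consecutive results."""

    x1: float
    x2: float
    delta_percent: float
    rcv_percent: float
    significant: bool
    direction: str  # "increase" | "decrease" | "none"


def _round_mode(rounding_mode: str) -> bool:
    if rounding_mode not in ROUNDING_MODES:
        raise ValueError(f"rounding_mode must be one of {ROUNDING_MODES}")
    return rounding_mode == "worked_example"


def compute_prri(
    series: MeasurementSeries,
    mode: str = "own_data",
    cv_i: float | None = None,
    level: float = 0.95,
    rounding_mode: str = "full_precision",
    force: bool = False,
    alpha: float = 0.05,
) -> IntervalResult:
    """Personalized reference interval from an individual's serial results.

    Parameters
    ----------
    mode:
        ``"own_data"`` — scenario-4 PI from the series' own mean and SD;
        requires n >= 5 and a clean quality screen (``force=True``
        overrides a failed screen).
        ``"cvi_based"`` — scenario-2 PI from the series mean with
        SD = CV_I·mean/100; requires n >= 3 and ``cv_i``.
    cv_i:
        Population within-subject biological variation, in percent
        (e.g. from the EFLM biological-variation database).
    rounding_mode:
        ``"full_precision"`` keeps every intermediate at machine
        precision.  ``"worked_example"`` emulates a desk calculation:
        summary statistics rounded to 2 decimals and the critical value
        rounded to 2 decimals, as read from a printed table.
    """
    table = _round_mode(rounding_mode)
    n = len(series)
    if mode == "own_data":
        if n < MIN_N_OWN_DATA:
            raise ValueError(
                "an own-data prRI requires a minimum of five measurement "
                f"results; got n = {n}"
            )
        report = assess_quality(series, alpha=alpha)
        if not report.passed and not force:
            reasons = []
            if report.outlier_index is not None:
                reasons.append(f"outlier at index {report.outlier_index}")
            if report.trend_p <= report.alpha:
                reasons.append(f"significant trend (p = {report.trend_p:.4g})")
            raise ValueError(
                "series failed quality screening (" + "; ".join(reasons)
                + "); pass force=True to compute anyway"
            )
        stats = summarize(series)
        if table:
            stats = stats.rounded(2)
        mult = t_quantile(n - 1, level)
        return pi_scenario4(
            stats.mean, stats.sd, n, level,
            multiplier=round(mult, 2) if table else mult,
        )
    if mode == "cvi_based":
        if cv_i is None:
            raise ValueError("cvi_based mode requires cv_i (percent)")
        if cv_i < 0:
            raise ValueError("cv_i must be non-negative")
        if n < MIN_N_CVI:
            raise ValueError(
                f"a CV_I-based prRI requires at least {MIN_N_CVI} results"
            )
        mean = sum(series.values) / n
        if table:
            mean = round(mean, 2)
        sd = cv_i * mean / 100.0
        if table:
            sd = round(sd, 2)
        mult = z_quantile(level)
        return pi_scenario2(
            mean, sd, n, level,
            multiplier=round(mult, 2) if table else mult,
        )
    raise ValueError(f"unknown prRI mode {mode!r}")


def rcv_conventional(
    cv_a: float, cv_i: float, level: float = 0.95
) -> float:
    """Conventional RCV in percent: ``z·√2·√(CV_A² + CV_I²)``.

    Uses the population within-subject CV_I, so the threshold is the same
    for every individual.
    """
    if cv_a < 0 or cv_i < 0:
        raise ValueError("CVs must be non-negative")
    return z_quantile(level) * math.sqrt(2.0) * math.hypot(cv_a, cv_i)


def rcv_personalized(
    cv: float,
    n: int,
    level: float = 0.95,
    cv_kind: str = "cv_t",
    rounding_mode: str = "full_precision",
) -> float:
    """Personalized RCV in percent: ``t(n−1)·√2·CV``.

    ``cv`` is the individual's within-person CV_P, or equivalently the
    total CV_T of the repeated results (which already folds in analytical
    variation) — the formula is identical, ``cv_kind`` only records which
    was supplied.  ``rounding_mode="worked_example"`` rounds the t value
    to 2 decimals as read from a printed table.
    """
    if cv_kind not in ("cv_p", "cv_t"):
        raise ValueError("cv_kind must be 'cv_p' or 'cv_t'")
    if cv < 0:
        raise ValueError("CV must be non-negative")
    if n < 2:
        raise ValueError("personalized RCV needs n >= 2 for the t multiplier")
    t = t_quantile(n - 1, level)
    if _round_mode(rounding_mode):
        t = round(t, 2)
    return t * math.sqrt(2.0) * cv


def delta_percent(x1: float, x2: float) -> float:
    """Signed percentage change between consecutive results, baseline
    denominator: ``100·(x1 − x2)/x1`` (negative for an increase)."""
    if x1 <= 0:
        raise ValueError("baseline result x1 must be positive")
    return 100.0 * (x1 - x2) / x1


def evaluate_change(
    x1: float, x2: float, rcv_percent: float
) -> ChangeAssessment:
    """Compare |Δ%| against an RCV threshold and report the verdict."""
    if rcv_percent < 0:
        raise ValueError("RCV must be non-negative")
    delta = delta_percent(x1, x2)
    if x2 > x1:
        direction = "increase"
    elif x2 < x1:
        direction = "decrease"
    else:
        direction = "none"
    return ChangeAssessment(
        x1=x1,
        x2=x2,
        delta_percent=delta,
        rcv_percent=rcv_percent,
        significant=abs(delta) > rcv_percent,
        direction=direction,
    )
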