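"""Internal-quality-control (IQC) monitoring with prediction intervals.

A data-collection period on a stable instrument yields a QC baseline:
with n >= 30 results the mean and SD are treated as population values and
the limits are ``mean ± z·SD`` (established regime, scenario 1); with
fewer results the limits are the scenario-4 PI ``mean ± t·SD·√(1+1/n)``
(provisional regime — a new instrument still in verification).  New QC
results are accepted when inside the closed interval and flagged
otherwise, which is the Levey-Jennings "within mean ± kSD" rule with an
explicit probability level.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from math import isfinite

import numpy as np
import pandas as pd

from .intervals import (
    IntervalResult,
    SummaryStats,
    pi_scenario1,
    pi_scenario4,
    summarize,
    t_quantile,
    z_quantile,
)
from .series import MeasurementSeries

__all__ = [
    "QCBaseline",
    "QCFlag",
    "establish_baseline",
    "evaluate_qc_result",
    "levey_jennings_points",
    "coverage_simulation",
    "save_baseline",
    "load_baseline",
]

#: Default series length at which the baseline regime switches from the
#: provisional t-based PI to the established z-based PI.
ESTABLISHED_MIN_N = 30
#: Minimum series length to establish any baseline.
MIN_BASELINE_N = 5


@dataclass(frozen=True)
class QCBaseline:
    """Frozen QC limits from a data-collection period."""

    stats: SummaryStats
    interval: IntervalResult
    regime: str  # "established" | "provisional"
    level: float
    unit: str


@dataclass(frozen=True)
class QCFlag:
    """Accept/flag decision for one new QC result."""

    value: float
    verdict: str  # "accept" | "flag"
    z_score: float
    rule: str


def establish_baseline(
    series: MeasurementSeries,
    level: float = 0.95,
    established_min_n: int = ESTABLISHED_MIN_N,
    rounding_mode: str = "full_precision",
) -> QCBaseline:
    """Compute QC limits from a data-collection series.

    ``rounding_mode="worked_example"`` rounds the summary statistics (and
    any t value) to 2 decimals before the interval formula, matching a
    bench calculation from a printed worksheet.
    """
    n = len(series)
    if n < MIN_BASELINE_N:
        raise ValueError(
            f"a QC baseline requires at least {MIN_BASELINE_N} results, got {n}"
        )
    stats = summarize(series)
    table = rounding_mode == "worked_example"
    if table:
        stats = stats.rounded(2)
    elif rounding_mode != "full_precision":
        raise ValueError(f"unknown rounding_mode {rounding_mode!r}")
    if n >= established_min_n:
        z = z_quantile(level)
        interval = pi_scenario1(
            stats.mean, stats.sd, level,
            multiplier=round(z, 2) if table else z,
        )
        regime = "established"
    else:
        t = t_quantile(n - 1, level)
        interval = pi_scenario4(
            stats.mean, stats.sd, n, level,
            multiplier=round(t, 2) if table else t,
        )
        regime = "provisional"
    return QCBaseline(
        stats=stats, interval=interval, regime=regime, level=level,
        unit=series.unit,
    )


def evaluate_qc_result(baseline: QCBaseline, value: float) -> QCFlag:
    """Accept the result iff it lies inside the baseline's closed PI.

    The z-score (value − mean)/SD is reported either way so the result
    can be placed on a Levey-Jennings chart.
    """
    if not isfinite(value):
        raise ValueError("QC result must be finite")
    z = (value - baseline.stats.mean) / baseline.stats.sd
    interval = baseline.interval
    if interval.contains(value):
        verdict = "accept"
        rule = (
            f"within {baseline.level:.0%} PI "
            f"[{interval.lower:.4g}, {interval.upper:.4g}]"
        )
    else:
        verdict = "flag"
        side = "below" if value < interval.lower else "above"
        limit = interval.lower if value < interval.lower else interval.upper
        rule = f"{side} {baseline.level:.0%} PI limit {limit:.4g}"
    return QCFlag(value=value, verdict=verdict, z_score=z, rule=rule)


def levey_jennings_points(
    baseline: QCBaseline, series: MeasurementSeries
) -> pd.DataFrame:
    """Chart-ready points for a Levey-Jennings plot.

    One row per result, in input order: ``time_index``, ``value``, the
    z-score against the baseline mean/SD, and the SD band the point falls
    in (``within_1sd``, ``1_2sd``, ``2_3sd`` or ``beyond_3sd``).
    """
    if series.unit != baseline.unit:
        raise ValueError(
            f"unit mismatch: baseline {baseline.unit!r} vs series "
            f"{series.unit!r}"
        )
    values = np.asarray(series.values)
    z = (values - baseline.stats.mean) / baseline.stats.sd
    abs_z = np.abs(z)
    band = np.select(
        [abs_z <= 1, abs_z <= 2, abs_z <= 3],
        ["within_1sd", "1_2sd", "2_3sd"],
        default="beyond_3sd",
    )
    return pd.DataFrame(
        {
            "time_index": list(series.time_index),
            "value": values,
            "z_score": z,
            "band": band,
        }
    )


def coverage_simulation(
    scenario_number: int,
    n: int,
    level: float = 0.95,
    reps: int = 100_000,
    seed: int = 0,
    true_mean: float = 0.0,
    true_sd: float = 1.0,
) -> float:
    """Monte-Carlo coverage of a PI scenario for an i.i.d. normal process.

    Each replicate draws n baseline results from Normal(true_mean,
    true_sd²), builds the scenario's PI (using the true parameters where
    the scenario declares them population-known), draws one fresh result,
    and checks membership.  Returns the fraction of replicates whose
    fresh result fell inside — nominally ``level``; exactly ``level`` in
    theory for scenarios 1, 2 and 4.
    """
    if reps < 1000:
        raise ValueError("use at least 1000 replicates")
    if scenario_number not in (1, 2, 3, 4):
        raise ValueError(f"unknown scenario {scenario_number}")
    if scenario_number != 1 and n < 2:
        raise ValueError("sample-based scenarios need n >= 2")
    rng = np.random.default_rng(seed)
    future = rng.normal(true_mean, true_sd, size=reps)
    if scenario_number == 1:
        half = z_quantile(level) * true_sd
        centers = np.full(reps, true_mean)
    else:
        baseline = rng.normal(true_mean, true_sd, size=(reps, n))
        means = baseline.mean(axis=1)
        sds = baseline.std(axis=1, ddof=1)
        if scenario_number == 2:
            centers = means
            half = z_quantile(level) * true_sd * np.sqrt(1.0 + 1.0 / n)
        elif scenario_number == 3:
            centers = np.full(reps, true_mean)
            half = t_quantile(n - 1, level) * sds
        else:
            centers = means
            half = t_quantile(n - 1, level) * sds * np.sqrt(1.0 + 1.0 / n)
    inside = np.abs(future - centers) <= half
    return float(inside.mean())


def save_baseline(baseline: QCBaseline, path) -> None:
    """Persist a baseline as a JSON document."""
    doc = {
        "stats": asdict(baseline.stats),
        "interval": asdict(baseline.interval),
        "regime": baseline.regime,
        "level": baseline.level,
        "unit": baseline.unit,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_baseline(path) -> QCBaseline:
    """Load a baseline saved by :func:`save_baseline`."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return QCBaseline(
        stats=SummaryStats(**doc["stats"]),
        interval=IntervalResult(**doc["interval"]),
        regime=doc["regime"],
        level=doc["level"],
        unit=doc["unit"],
    )
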