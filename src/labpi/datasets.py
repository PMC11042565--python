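"""Worked-example fixtures and a seeded synthetic-series generator.

The fixture tables are the hypothetical glucose/cholesterol datasets used
throughout the worked examples — IQC collection runs (tables 1, 3, 4),
an individual's sparse sampling occasions (table 2), an individual's
weekly monitoring series (table 5) and a two-day consecutive-result pair
with population reference intervals (table 6).  Values are stored exactly
as printed, including each table's printed summary row (which is rounded
to two decimals and in one case differs slightly from the full-precision
recomputation).

:func:`generate_series` produces series with the structure the
prediction-interval model assumes: a homeostatic set point plus i.i.d.
normal noise from within-person and analytical variation combined in
quadrature, with an optional linear drift and an optional injected
outlier for exercising the quality screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import MeasurementSeries

__all__ = [
    "GeneratorSpec",
    "fixture_table",
    "generate_series",
    "PRINTED_SUMMARIES",
    "TABLE2_CVI_PERCENT",
    "TABLE3_PEER_GROUP_MEAN",
]

_TABLE1 = (
    4.22, 4.27, 4.27, 4.22, 4.27, 4.16, 4.22, 4.33, 4.27, 4.22,
    4.16, 4.22, 4.16, 4.11, 4.05, 4.22, 4.16, 4.22, 4.11, 4.33,
    4.22, 4.27, 4.11, 4.16, 4.27, 4.16, 4.33, 4.33, 4.22, 4.16,
)
_TABLE2 = (4.20, 4.23, 4.15, 4.25)
_TABLE3 = (4.12, 4.23, 4.26, 4.17, 4.22, 4.20, 4.13, 4.17, 4.15, 4.13)
_TABLE4 = (
    4.16, 4.33, 4.22, 4.27, 4.22, 4.16, 4.33, 4.22, 4.16, 4.33,
    4.16, 4.22, 4.33, 4.22,
)
_TABLE5_GLUCOSE = (4.16, 4.33, 4.22, 4.61, 4.11, 4.27, 4.50, 4.22, 4.16, 4.33)
_TABLE5_CHOLESTEROL = (3.68, 3.89, 3.81, 3.76, 3.91, 3.63, 3.83, 3.73, 3.81, 3.68)

#: Summary rows exactly as printed under each table (mean, SD, CV%).
#: These are 2-decimal desk values; e.g. the table-5 cholesterol mean is
#: printed as 3.76 while the ten values average 3.773, and the table-1 CV
#: 1.66% follows from the rounded SD rather than the full-precision one.
PRINTED_SUMMARIES: dict[str, dict[str, float]] = {
    "table1": {"mean": 4.21, "sd": 0.07, "cv_percent": 1.66},
    "table2": {"mean": 4.21, "sd": 0.21, "cv_percent": 5.00},
    "table3": {"mean": 4.20, "sd": 0.05, "cv_percent": 1.14},
    "table4": {"mean": 4.24, "sd": 0.07, "cv_percent": 1.65},
    "table5_glucose": {"mean": 4.29, "sd": 0.16, "cv_percent": 3.73},
    "table5_cholesterol": {"mean": 3.76, "sd": 0.09, "cv_percent": 2.39},
}

#: Within-subject biological variation of glucose used in the sparse-data
#: prRI example (an EFLM-database style population value, percent).
TABLE2_CVI_PERCENT = 5.00
#: Peer-group (inter-laboratory) assigned mean used in the
#: external-mean/sample-variance example, mmol/L.
TABLE3_PEER_GROUP_MEAN = 4.20


def fixture_table(name: str):
    """Return a worked-example table by name.

    ``table1``–``table4`` return a single :class:`MeasurementSeries`;
    ``table5`` returns ``{"glucose": ..., "cholesterol": ...}``;
    ``table6`` returns a DataFrame of the day-1/day-2 result pairs with
    their population-based reference intervals.
    """
    if name == "table1":
        return MeasurementSeries("table1_iqc_glucose", _TABLE1)
    if name == "table2":
        return MeasurementSeries("table2_glucose", _TABLE2)
    if name == "table3":
        return MeasurementSeries("table3_qc_glucose", _TABLE3)
    if name == "table4":
        return MeasurementSeries("table4_iqc_glucose", _TABLE4)
    if name == "table5":
        return {
            "glucose": MeasurementSeries("glucose", _TABLE5_GLUCOSE),
            "cholesterol": MeasurementSeries("cholesterol", _TABLE5_CHOLESTEROL),
        }
    if name == "table6":
        return pd.DataFrame(
            {
                "measurand": ["glucose", "cholesterol"],
                "day1": [4.22, 3.76],
                "day2": [5.11, 4.40],
                "ref_low": [3.88, 2.33],
                "ref_high": [5.55, 5.18],
                "unit": ["mmol/L", "mmol/L"],
            }
        )
    raise ValueError(f"unknown fixture table {name!r} (table1..table6)")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a synthetic monitoring series.

    ``set_point`` is the homeostatic central value; ``cv_p`` and ``cv_a``
    (percent) are the within-person biological and analytical variations,
    combined in quadrature into the noise SD; ``trend_slope`` adds a
    linear drift per occasion; ``outlier`` injects a single shifted point
    as ``(index, magnitude_in_sd_units)``.
    """

    set_point: float
    cv_p: float
    cv_a: float
    n: int
    seed: int
    trend_slope: float = 0.0
    outlier: tuple[int, float] | None = None
    series_id: str = "synthetic"
    unit: str = "mmol/L"

    def __post_init__(self) -> None:
        if self.cv_p < 0 or self.cv_a < 0:
            raise ValueError("cv_p and cv_a must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.outlier is not None:
            idx, _ = self.outlier
            if not 0 <= idx < self.n:
                raise ValueError("outlier index out of range")

    @property
    def noise_sd(self) -> float:
        """Total noise SD: set_point·√(cv_p² + cv_a²)/100."""
        return self.set_point * math.hypot(self.cv_p, self.cv_a) / 100.0


def generate_series(spec: GeneratorSpec) -> MeasurementSeries:
    """Simulate a series from a :class:`GeneratorSpec`; deterministic per
    seed."""
    rng = np.random.default_rng(spec.seed)
    occasions = np.arange(1, spec.n + 1)
    values = (
        spec.set_point
        + spec.trend_slope * occasions
        + rng.normal(0.0, spec.noise_sd, size=spec.n)
    )
    if spec.outlier is not None:
        idx, magnitude = spec.outlier
        values[idx] += magnitude * spec.noise_sd
    return MeasurementSeries(
        series_id=spec.series_id,
        values=tuple(float(v) for v in values),
        time_index=tuple(int(t) for t in occasions),
        unit=spec.unit,
    )
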