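"""Containers for serial laboratory measurements.

A :class:`MeasurementSeries` holds one ordered stream of quantitative
results — daily internal-quality-control (IQC) values for one control lot,
or one patient's serial results for a single measurand.  Series are read
from and written to long-format CSV with columns
``series_id,time_index,value,unit``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

CSV_COLUMNS = ["series_id", "time_index", "value", "unit"]


@dataclass(frozen=True)
class MeasurementSeries:
    """Ordered results for one series (one QC lot or one patient measurand).

    Parameters
    ----------
    series_id:
        Free-text label, e.g. ``"glucose"``.
    values:
        Concentrations in a single unit, in measurement order.
    time_index:
        Strictly increasing 1-based occasion numbers (days or weeks).
        Defaults to ``1..n`` when omitted.
    unit:
        Unit of all values, e.g. ``"mmol/L"``.
    """

    series_id: str
    values: tuple[float, ...]
    time_index: tuple[int, ...] = field(default=())
    unit: str = "mmol/L"

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        if len(values) == 0:
            raise ValueError("a measurement series needs at least one value")
        if not all(math.isfinite(v) for v in values):
            raise ValueError("all measurement values must be finite")
        time_index = tuple(int(t) for t in self.time_index) or tuple(
            range(1, len(values) + 1)
        )
        if len(time_index) != len(values):
            raise ValueError("time_index and values must have equal length")
        if any(b <= a for a, b in zip(time_index, time_index[1:])):
            raise ValueError("time_index must be strictly increasing")
        if not self.unit:
            raise ValueError("unit must be non-empty")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "time_index", time_index)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame view (one row per result)."""
        return pd.DataFrame(
            {
                "series_id": self.series_id,
                "time_index": list(self.time_index),
                "value": list(self.values),
                "unit": self.unit,
            }
        )


def write_csv(series: MeasurementSeries | list[MeasurementSeries], path) -> None:
    """Write one or more series to a long-format CSV file."""
    if isinstance(series, MeasurementSeries):
        series = [series]
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    frame.to_csv(path, index=False)


def read_csv(path, series_id: str | None = None) -> MeasurementSeries:
    """Read one series from a long-format CSV file.

    ``series_id`` selects a series when the file holds several; it may be
    omitted for a single-series file.
    """
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"CSV is missing required columns: {missing}")
    ids = frame["series_id"].unique().tolist()
    if series_id is None:
        if len(ids) != 1:
            raise ValueError(f"file holds several series {ids}; pass series_id")
        series_id = ids[0]
    sub = frame[frame["series_id"] == series_id]
    if sub.empty:
        raise ValueError(f"series {series_id!r} not found (available: {ids})")
    units = sub["unit"].unique().tolist()
    if len(units) != 1:
        raise ValueError(f"series {series_id!r} mixes units: {units}")
    sub = sub.sort_values("time_index")
    return MeasurementSeries(
        series_id=str(series_id),
        values=tuple(sub["value"].astype(float)),
        time_index=tuple(sub["time_index"].astype(int)),
        unit=str(units[0]),
    )


def read_all_csv(path) -> dict[str, MeasurementSeries]:
    """Read every series in a long-format CSV file, keyed by series id."""
    frame = pd.read_csv(path)
    return {
        str(sid): read_csv(path, series_id=str(sid))
        for sid in frame["series_id"].unique()
    }
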