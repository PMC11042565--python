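"""Statistical kernel: summary statistics, z/t multipliers, and the four
prediction-interval scenarios plus the confidence interval.

The prediction interval (PI) for a single future result from a stable
process is ``center ± k · dispersion``, where the center and the dispersion
may each come from the *population* (known, external) or from a *sample*
(estimated from n prior results).  The four provenance combinations give
four scenarios:

==========  ===============  ==================  ==========  ===============
scenario    mean             variance            multiplier  half-width
==========  ===============  ==================  ==========  ===============
1           population (µ)   population (σ²)     z           z·σ
2           sample (X̄, n)    population (σ²)     z           z·σ·√(1+1/n)
3           population (µ)   sample (s², n)      t(n−1)      t·s
4           sample (X̄, n)    sample (s², n)      t(n−1)      t·s·√(1+1/n)
==========  ===============  ==================  ==========  ===============

A population variance pairs with the standard-normal multiplier z; an
estimated variance pairs with Student's t at n−1 degrees of freedom.  The
√(1+1/n) factor carries the extra uncertainty of an estimated mean.  The
confidence interval (CI) for the mean itself is ``X̄ ± t·s/√n`` and is
always narrower than the matching PI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy import stats

from .series import MeasurementSeries

__all__ = [
    "SummaryStats",
    "Provenance",
    "ScenarioSpec",
    "IntervalResult",
    "summarize",
    "z_quantile",
    "t_quantile",
    "pi_scenario1",
    "pi_scenario2",
    "pi_scenario3",
    "pi_scenario4",
    "confidence_interval",
    "select_scenario",
]


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD and CV% of a series (the set point and its
    dispersion)."""

    n: int
    mean: float
    sd: float
    cv_percent: float

    def rounded(self, decimals: int = 2) -> "SummaryStats":
        """Stats rounded to ``decimals`` places, as printed in bench
        worksheets; CV is recomputed from the rounded mean and SD."""
        mean = round(self.mean, decimals)
        sd = round(self.sd, decimals)
        cv = 100.0 * sd / mean if mean != 0 else float("nan")
        return SummaryStats(n=self.n, mean=mean, sd=sd, cv_percent=round(cv, decimals))


class Provenance(str, Enum):
    """Origin of a distribution parameter: known population value or
    sample estimate."""

    POPULATION = "population"
    SAMPLE = "sample"


_SCENARIO_TABLE = {
    (Provenance.POPULATION, Provenance.POPULATION): 1,
    (Provenance.SAMPLE, Provenance.POPULATION): 2,
    (Provenance.POPULATION, Provenance.SAMPLE): 3,
    (Provenance.SAMPLE, Provenance.SAMPLE): 4,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Provenance pair and the scenario number / multiplier family it
    selects."""

    mean_provenance: Provenance
    variance_provenance: Provenance
    scenario_number: int
    multiplier_family: str  # "z" or "t"


@dataclass(frozen=True)
class IntervalResult:
    """A two-sided statistical interval ``[lower, upper]`` for a stated
    probability level."""

    lower: float
    upper: float
    level: float
    multiplier: float
    kind: str  # "prediction" or "confidence"
    scenario_number: int | None = None
    n_used: int | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower limit exceeds upper limit")

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2.0

    @property
    def center(self) -> float:
        return (self.upper + self.lower) / 2.0

    def contains(self, value: float) -> bool:
        """Closed-endpoint membership: a value exactly on a limit is inside."""
        return self.lower <= value <= self.upper

    def rounded(self, decimals: int = 2) -> "IntervalResult":
        return IntervalResult(
            lower=round(self.lower, decimals),
            upper=round(self.upper, decimals),
            level=self.level,
            multiplier=self.multiplier,
            kind=self.kind,
            scenario_number=self.scenario_number,
            n_used=self.n_used,
        )


def summarize(series: MeasurementSeries) -> SummaryStats:
    """Arithmetic mean, sample SD (n−1 denominator) and CV% of a series.

    Raises
    ------
    ValueError
        If the series has a single value (SD undefined) or zero mean
        (CV undefined).
    """
    n = len(series)
    if n < 2:
        raise ValueError("sample SD needs at least two results (n >= 2)")
    mean = sum(series.values) / n
    ss = sum((v - mean) ** 2 for v in series.values)
    sd = math.sqrt(ss / (n - 1))
    if mean == 0:
        raise ValueError("CV is undefined for a zero mean")
    return SummaryStats(n=n, mean=mean, sd=sd, cv_percent=100.0 * sd / mean)


def _check_level(level: float) -> None:
    if not 0.0 < level < 1.0:
        raise ValueError(f"probability level must be in (0, 1), got {level}")


def z_quantile(level: float) -> float:
    """Two-sided standard-normal multiplier; 1.96 at the 95% level."""
    _check_level(level)
    return float(stats.norm.ppf(0.5 + level / 2.0))


def t_quantile(df: int, level: float) -> float:
    """Two-tailed Student-t critical value at ``df`` degrees of freedom.

    Decreases monotonically in ``df`` toward :func:`z_quantile` — e.g.
    2.776 at df 4, 2.26 at df 9, 2.04 at df 29, 1.96 in the limit.
    """
    _check_level(level)
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.t.ppf(0.5 + level / 2.0, df))


def _resolve_z(level: float, multiplier: float | None) -> float:
    return z_quantile(level) if multiplier is None else float(multiplier)


def _resolve_t(n: int, level: float, multiplier: float | None) -> float:
    return t_quantile(n - 1, level) if multiplier is None else float(multiplier)


def _interval(
    center: float,
    half_width: float,
    level: float,
    multiplier: float,
    kind: str,
    scenario: int | None,
    n: int | None,
) -> IntervalResult:
    return IntervalResult(
        lower=center - half_width,
        upper=center + half_width,
        level=level,
        multiplier=multiplier,
        kind=kind,
        scenario_number=scenario,
        n_used=n,
    )


def pi_scenario1(
    pop_mean: float,
    pop_sd: float,
    level: float = 0.95,
    multiplier: float | None = None,
) -> IntervalResult:
    """PI with known population mean and SD: ``µ ± z·σ``.

    The √(1+1/n) inflation is dropped because a population SD implies a
    large n.  ``multiplier`` overrides z (e.g. the bench approximation 2.00).
    """
    if pop_sd < 0:
        raise ValueError("population SD must be non-negative")
    z = _resolve_z(level, multiplier)
    return _interval(pop_mean, z * pop_sd, level, z, "prediction", 1, None)


def pi_scenario2(
    sample_mean: float,
    pop_sd: float,
    n: int,
    level: float = 0.95,
    multiplier: float | None = None,
) -> IntervalResult:
    """PI with sample mean of n results and population SD:
    ``X̄ ± z·σ·√(1+1/n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if pop_sd < 0:
        raise ValueError("population SD must be non-negative")
    z = _resolve_z(level, multiplier)
    return _interval(
        sample_mean, z * pop_sd * math.sqrt(1.0 + 1.0 / n), level, z,
        "prediction", 2, n,
    )


def pi_scenario3(
    pop_mean: float,
    sample_sd: float,
    n: int,
    level: float = 0.95,
    inflate: bool = False,
    multiplier: float | None = None,
) -> IntervalResult:
    """PI with known population mean and sample SD from n results:
    ``µ ± t(n−1)·s``.

    With ``inflate=True`` the half-width is multiplied by √(1+1/n); the
    default omits it, treating the external mean as exact.
    """
    if n < 2:
        raise ValueError("sample SD needs n >= 2")
    if sample_sd < 0:
        raise ValueError("sample SD must be non-negative")
    t = _resolve_t(n, level, multiplier)
    half = t * sample_sd
    if inflate:
        half *= math.sqrt(1.0 + 1.0 / n)
    return _interval(pop_mean, half, level, t, "prediction", 3, n)


def pi_scenario4(
    sample_mean: float,
    sample_sd: float,
    n: int,
    level: float = 0.95,
    multiplier: float | None = None,
) -> IntervalResult:
    """PI with sample mean and sample SD: ``X̄ ± t(n−1)·s·√(1+1/n)``.

    This is the fully empirical case — the basis for personalized
    reference intervals from an individual's own serial results and for
    provisional QC limits on a new instrument.
    """
    if n < 2:
        raise ValueError("sample SD needs n >= 2")
    if sample_sd < 0:
        raise ValueError("sample SD must be non-negative")
    t = _resolve_t(n, level, multiplier)
    return _interval(
        sample_mean, t * sample_sd * math.sqrt(1.0 + 1.0 / n), level, t,
        "prediction", 4, n,
    )


def confidence_interval(
    sample_mean: float,
    sample_sd: float,
    n: int,
    level: float = 0.95,
    multiplier: float | None = None,
) -> IntervalResult:
    """CI for the mean itself: ``X̄ ± t(n−1)·s/√n``; narrower than any PI
    built from the same data."""
    if n < 2:
        raise ValueError("sample SD needs n >= 2")
    if sample_sd < 0:
        raise ValueError("sample SD must be non-negative")
    t = _resolve_t(n, level, multiplier)
    return _interval(
        sample_mean, t * sample_sd / math.sqrt(n), level, t,
        "confidence", None, n,
    )


def select_scenario(
    mean_provenance: str | Provenance,
    variance_provenance: str | Provenance,
) -> ScenarioSpec:
    """Map the (mean, variance) provenance pair to its scenario number and
    multiplier family (z for a population variance, t for a sample one)."""
    mp = Provenance(mean_provenance)
    vp = Provenance(variance_provenance)
    number = _SCENARIO_TABLE[(mp, vp)]
    family = "z" if vp is Provenance.POPULATION else "t"
    return ScenarioSpec(
        mean_provenance=mp,
        variance_provenance=vp,
        scenario_number=number,
        multiplier_family=family,
    )
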