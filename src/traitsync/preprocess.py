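"""Brood-record filtering, annual aggregation, detrending, and normalization.

The raw observations are individual nesting attempts ("broods") from
long-term nest-box monitoring of hole-nesting passerines.  Synchrony is
analysed at the level of annual population averages, so this module turns
brood tables into :class:`~traitsync.panels.TraitPanel` objects:

1. keep first clutches of non-experimental broods, with the trait of
   interest recorded, in population-years with at least two broods;
2. aggregate per population-year (median for laying date, whose annual
   distribution is right-skewed; arithmetic mean otherwise);
3. remove each population's linear time trend and scale residuals to unit
   variance, so synchrony measures year-to-year fluctuation rather than
   shared long-term trends or absolute between-population differences.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegeneratePopulationError,
    UndefinedCVError,
    ValidationError,
)
from .panels import TRAIT_NAMES, TraitPanel

FLEDGLING_TRAITS = ("fledgling_number", "fledgling_success")

_DEGENERATE_SD_TOL = 1e-12


@dataclass(frozen=True)
class BroodRecord:
    """One nesting attempt.

    ``laying_date`` is an integer day offset with April 1 = 1; dates before
    April 1 are zero or negative (26 March = -5).  Missing trait values are
    ``None``.
    """

    population_id: str
    year: int
    laying_date: int | None = None
    clutch_size: int | None = None
    fledgling_number: int | None = None
    is_first_clutch: bool = True
    is_experimental: bool = False

    def __post_init__(self):
        if not 1900 <= self.year <= 2100:
            raise ValidationError(f"{self!r}: year {self.year} outside [1900, 2100]")
        if self.clutch_size is not None and self.clutch_size < 0:
            raise ValidationError(f"{self!r}: negative clutch_size")
        if self.fledgling_number is not None and self.fledgling_number < 0:
            raise ValidationError(f"{self!r}: negative fledgling_number")
        if (
            self.clutch_size is not None
            and self.fledgling_number is not None
            and self.fledgling_number > self.clutch_size
        ):
            raise ValidationError(
                f"{self!r}: fledgling_number {self.fledgling_number} exceeds "
                f"clutch_size {self.clutch_size}"
            )


@dataclass(frozen=True)
class Population:
    """A monitored population: one species at one study site."""

    population_id: str
    species: str
    latitude: float
    longitude: float

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"{self.population_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"{self.population_id}: longitude {self.longitude} out of range")


@dataclass(frozen=True)
class FilterRules:
    """Brood inclusion rules for one target trait.

    The fledgling rule (``fledgling_min``, default: at least one fledgling,
    which excludes complete brood losses from predation or other external
    causes) applies only when the target trait is a fledgling trait.
    """

    trait: str
    min_broods_per_year: int = 2
    fledgling_min: int = 1

    def __post_init__(self):
        if self.trait not in TRAIT_NAMES:
            raise ConfigurationError(f"unknown trait {self.trait!r}; expected one of {TRAIT_NAMES}")


def trait_value(record: BroodRecord, trait: str) -> float | None:
    """The per-brood value of ``trait``, or None if not computable."""
    if trait == "laying_date":
        return None if record.laying_date is None else float(record.laying_date)
    if trait == "clutch_size":
        return None if record.clutch_size is None else float(record.clutch_size)
    if trait == "fledgling_number":
        return None if record.fledgling_number is None else float(record.fledgling_number)
    if trait == "fledgling_success":
        if record.clutch_size is None or record.fledgling_number is None:
            return None
        if record.clutch_size == 0:
            raise ValidationError(f"{record!r}: fledgling_success undefined for clutch_size 0")
        return record.fledgling_number / record.clutch_size
    raise ConfigurationError(f"unknown trait {trait!r}; expected one of {TRAIT_NAMES}")


def filter_broods(records: Sequence[BroodRecord], rules: FilterRules) -> list[BroodRecord]:
    """Apply the brood inclusion rules, preserving record order.

    Keeps first clutches of non-experimental broods with the target trait
    recorded; for fledgling traits additionally requires
    ``fledgling_number >= rules.fledgling_min``.  Population-years left with
    fewer than ``rules.min_broods_per_year`` broods are then dropped
    entirely (the two-broods rule is re-applied after the record-level
    filters).  An empty result is not an error.
    """
    if len(records) == 0:
        raise ValidationError("filter_broods: empty record list")
    kept = []
    for rec in records:
        if not rec.is_first_clutch or rec.is_experimental:
            continue
        if trait_value(rec, rules.trait) is None:
            continue
        if rules.trait in FLEDGLING_TRAITS and (
            rec.fledgling_number is None or rec.fledgling_number < rules.fledgling_min
        ):
            continue
        kept.append(rec)
    counts: dict[tuple[str, int], int] = {}
    for rec in kept:
        key = (rec.population_id, rec.year)
        counts[key] = counts.get(key, 0) + 1
    return [r for r in kept if counts[(r.population_id, r.year)] >= rules.min_broods_per_year]


def annual_average(records: Sequence[BroodRecord], trait: str) -> TraitPanel:
    """Aggregate filtered broods into annual average trait values.

    Laying date is aggregated by the median (annual laying-date
    distributions are right-skewed, making the median the better measure of
    central tendency); clutch size and fledgling number by the arithmetic
    mean; fledgling success by the mean of per-brood fledgling/clutch
    ratios.  The mask is true exactly for population-years with at least two
    contributing broods.
    """
    if trait not in TRAIT_NAMES:
        raise ConfigurationError(f"unknown trait {trait!r}; expected one of {TRAIT_NAMES}")
    cells: dict[tuple[str, int], list[float]] = {}
    for rec in records:
        v = trait_value(rec, trait)
        if v is not None:
            cells.setdefault((rec.population_id, rec.year), []).append(v)
    cells = {k: v for k, v in cells.items() if len(v) >= 2}
    if not cells:
        raise ValidationError(f"no population-year has >= 2 broods with {trait!r} recorded")
    pops = sorted({k[0] for k in cells})
    years = sorted({k[1] for k in cells})
    values = np.full((len(pops), len(years)), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    agg = np.median if trait == "laying_date" else np.mean
    for (pop, year), vals in cells.items():
        i, j = pops.index(pop), years.index(year)
        values[i, j] = agg(vals)
        mask[i, j] = True
    return TraitPanel(name=trait, populations=pops, years=years, values=values, mask=mask)


def _window_days(year: int, months: frozenset[int]) -> int:
    return sum(calendar.monthrange(year, m)[1] for m in months)


def seasonal_mean(
    daily: Iterable[tuple[_dt.date | str, float]],
    months: frozenset[int] | set[int] = frozenset({2, 3, 4, 5}),
    max_missing_frac: float = 0.10,
) -> pd.Series:
    """Annual means of a daily series over a within-year month window.

    The default window, February-May, is the period before and during
    breeding that drives laying decisions.  Years missing more than
    ``max_missing_frac`` of the window's days (default 10%) are dropped as
    incomplete; leap years average 121 days in the default window,
    non-leap years 120.

    Returns a :class:`pandas.Series` of means indexed by year.
    """
    months = frozenset(int(m) for m in months)
    if not months or not months.issubset(range(1, 13)):
        raise ValidationError(f"invalid month set {sorted(months)}")
    rows = list(daily)
    if not rows:
        raise ValidationError("seasonal_mean: empty daily series")
    dates = pd.to_datetime([d for d, _ in rows])
    vals = pd.Series([v for _, v in rows], index=dates, dtype=float).dropna()
    vals = vals[vals.index.month.isin(months)]
    out = {}
    for year, group in vals.groupby(vals.index.year):
        expected = _window_days(int(year), months)
        n_days = group.index.normalize().nunique()
        if expected - n_days <= max_missing_frac * expected:
            out[int(year)] = float(group.mean())
    return pd.Series(out, dtype=float).sort_index()


def detrend_normalize(panel: TraitPanel) -> TraitPanel:
    """Remove each population's linear time trend and scale to unit variance.

    Per population independently: ordinary least squares of annual value on
    calendar year over that population's observed years; residuals are
    divided by their sample standard deviation (n-1 denominator).  The
    output therefore has mean 0 and SD 1 within every population, and is
    invariant to adding any affine function of year to a population's
    series.  The availability mask is unchanged.
    """
    values = panel.values.copy()
    for i, pop in enumerate(panel.populations):
        obs = panel.mask[i]
        n = int(obs.sum())
        if n < 3:
            raise ValidationError(
                f"population {pop!r}: {n} observed years < 3 required for detrending"
            )
        years = np.asarray(panel.years, dtype=float)[obs]
        y = panel.values[i, obs]
        slope, intercept = np.polyfit(years, y, 1)
        resid = y - (intercept + slope * years)
        sd = resid.std(ddof=1)
        scale = max(1.0, float(np.abs(y).max()))
        if sd <= _DEGENERATE_SD_TOL * scale:
            raise DegeneratePopulationError(
                pop, "zero residual variance (series exactly linear in year)"
            )
        values[i, obs] = resid / sd
    return replace(panel, values=values)


def coefficient_of_variation(series) -> float:
    """Sample SD (n-1 denominator) divided by the mean."""
    x = np.asarray(list(series), dtype=float)
    if x.size < 2:
        raise ValidationError("coefficient_of_variation: need n >= 2")
    mean = x.mean()
    if mean == 0.0:
        raise UndefinedCVError("coefficient_of_variation undefined for zero mean")
    return float(x.std(ddof=1) / mean)
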