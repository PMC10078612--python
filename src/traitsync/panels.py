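"""Population x year panels of annual values with explicit missingness.

A panel holds one value per (population, year) cell plus a boolean
availability mask.  Trait panels and climate panels share the same shape
contract so that every downstream operation (detrending, residualization,
likelihood evaluation) can treat them uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

TRAIT_NAMES = ("laying_date", "clutch_size", "fledgling_number", "fledgling_success")


@dataclass
class Panel:
    """Populations x years array of annual values with an availability mask.

    Parameters
    ----------
    name
        Label of the quantity stored (a trait name or climate variable name).
    populations
        Ordered population identifiers (rows).
    years
        Ordered calendar years (columns).
    values
        Real array of shape ``(n_populations, n_years)``.  Cells where
        ``mask`` is False are ignored and stored as NaN.
    mask
        Boolean availability array of the same shape.
    """

    name: str
    populations: list[str]
    years: list[int]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.populations = [str(p) for p in self.populations]
        self.years = [int(y) for y in self.years]
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (len(self.populations), len(self.years))
        if self.values.shape != shape or self.mask.shape != shape:
            raise ValidationError(
                f"panel shape mismatch: values {self.values.shape}, "
                f"mask {self.mask.shape}, expected {shape}"
            )
        if len(set(self.populations)) != len(self.populations):
            raise ValidationError("duplicate population_id in panel")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValidationError("non-finite value in an observed (masked-true) cell")
        # Normalise hidden cells to NaN so equality is well defined.
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def years_observed(self) -> np.ndarray:
        """Number of observed years per population."""
        return self.mask.sum(axis=1)

    def subset_populations(self, keep: Sequence[str]) -> "Panel":
        keep = list(keep)
        missing = set(keep) - set(self.populations)
        if missing:
            raise ValidationError(f"unknown populations: {sorted(missing)}")
        idx = [self.populations.index(p) for p in keep]
        return replace(
            self,
            populations=keep,
            values=self.values[idx].copy(),
            mask=self.mask[idx].copy(),
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format view: columns population_id, year, value (observed cells only)."""
        rows = []
        for i, pop in enumerate(self.populations):
            for j, year in enumerate(self.years):
                if self.mask[i, j]:
                    rows.append((pop, year, self.values[i, j]))
        return pd.DataFrame(rows, columns=["population_id", "year", "value"])

    @classmethod
    def from_long(cls, df: pd.DataFrame, name: str) -> "Panel":
        """Build a panel from long-format records (population_id, year, value)."""
        required = {"population_id", "year", "value"}
        if not required.issubset(df.columns):
            raise ValidationError(f"long-format frame must have columns {sorted(required)}")
        if df.duplicated(["population_id", "year"]).any():
            raise ValidationError("duplicate (population_id, year) rows")
        pops = sorted(df["population_id"].astype(str).unique())
        years = sorted(int(y) for y in df["year"].unique())
        values = np.full((len(pops), len(years)), np.nan)
        mask = np.zeros_like(values, dtype=bool)
        pidx = {p: i for i, p in enumerate(pops)}
        yidx = {y: j for j, y in enumerate(years)}
        for pop, year, value in df[["population_id", "year", "value"]].itertuples(index=False):
            i, j = pidx[str(pop)], yidx[int(year)]
            values[i, j] = value
            mask[i, j] = True
        return cls(name=name, populations=pops, years=years, values=values, mask=mask)

    def equals(self, other: "Panel") -> bool:
        return (
            self.name == other.name
            and self.populations == other.populations
            and self.years == other.years
            and np.array_equal(self.mask, other.mask)
            and np.allclose(self.values[self.mask], other.values[other.mask], equal_nan=False)
        )


@dataclass
class TraitPanel(Panel):
    """Annual average trait values per population."""

    @property
    def trait_name(self) -> str:
        return self.name


@dataclass
class ClimatePanel(Panel):
    """Seasonal-window climate means per population, same shape contract as TraitPanel."""

    @property
    def variable_name(self) -> str:
        return self.name


def require_min_years(panel: Panel, min_years: int = 9) -> Panel:
    """Drop populations observed in fewer than ``min_years`` years.

    The long-term-study inclusion rule: only populations monitored for at
    least ``min_years`` (default 9) years enter the synchrony analysis.
    """
    if min_years < 1:
        raise ValidationError("min_years must be >= 1")
    counts = panel.years_observed()
    keep = [p for p, c in zip(panel.populations, counts) if c >= min_years]
    if not keep:
        raise ValidationError(f"no population has >= {min_years} observed years")
    return panel.subset_populations(keep)


def align_panels(a: Panel, b: Panel) -> tuple[Panel, Panel]:
    """Restrict two panels to their common populations and years, in sorted order."""
    pops = [p for p in a.populations if p in set(b.populations)]
    years = sorted(set(a.years) & set(b.years))
    if not pops or not years:
        raise ValidationError("panels share no populations or no years")

    def _take(panel: Panel) -> Panel:
        pi = [panel.populations.index(p) for p in pops]
        yi = [panel.years.index(y) for y in years]
        return replace(
            panel,
            populations=list(pops),
            years=list(years),
            values=panel.values[np.ix_(pi, yi)].copy(),
            mask=panel.mask[np.ix_(pi, yi)].copy(),
        )

    return _take(a), _take(b)
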