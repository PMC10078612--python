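"""Readers and writers for the package's delimited-text interfaces.

All files are comma-separated UTF-8 with a header row, ISO-8601 dates, and
"." as the decimal separator; empty fields mean missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panels import ClimatePanel, Panel, TraitPanel
from .preprocess import BroodRecord, Population, seasonal_mean
from .synchrony import SynchronyFit

BROOD_COLUMNS = [
    "population_id",
    "species",
    "year",
    "laying_date",
    "clutch_size",
    "fledgling_number",
    "is_first_clutch",
    "is_experimental",
]

_TRUTHY = {"true", "1", "t", "yes", "y"}
_FALSY = {"false", "0", "f", "no", "n"}


def _as_bool(x, column: str) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot parse boolean {x!r} in column {column}")


def _as_opt_int(x) -> int | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or str(x).strip() == "":
        return None
    return int(float(x))


def read_broods_csv(path) -> pd.DataFrame:
    """Read a brood table; returns the raw frame (use :func:`broods_from_frame`)."""
    df = pd.read_csv(path, dtype={"population_id": str, "species": str})
    missing = set(BROOD_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"brood CSV {path}: missing columns {sorted(missing)}")
    return df


def broods_from_frame(df: pd.DataFrame) -> list[BroodRecord]:
    """Convert brood rows to validated records (validation errors name the row)."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            BroodRecord(
                population_id=str(row.population_id),
                year=int(row.year),
                laying_date=_as_opt_int(row.laying_date),
                clutch_size=_as_opt_int(row.clutch_size),
                fledgling_number=_as_opt_int(row.fledgling_number),
                is_first_clutch=_as_bool(row.is_first_clutch, "is_first_clutch"),
                is_experimental=_as_bool(row.is_experimental, "is_experimental"),
            )
        )
    return records


def write_broods_csv(records: list[BroodRecord], species: str, path) -> None:
    rows = [
        {
            "population_id": r.population_id,
            "species": species,
            "year": r.year,
            "laying_date": r.laying_date,
            "clutch_size": r.clutch_size,
            "fledgling_number": r.fledgling_number,
            "is_first_clutch": r.is_first_clutch,
            "is_experimental": r.is_experimental,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=BROOD_COLUMNS).to_csv(path, index=False)


def read_sites_csv(path) -> list[Population]:
    df = pd.read_csv(path, dtype={"population_id": str, "species": str})
    required = {"population_id", "species", "latitude", "longitude"}
    if not required.issubset(df.columns):
        raise ValidationError(f"sites CSV {path}: missing columns {sorted(required - set(df.columns))}")
    return [
        Population(str(r.population_id), str(r.species), float(r.latitude), float(r.longitude))
        for r in df.itertuples(index=False)
    ]


def write_sites_csv(populations: list[Population], path) -> None:
    pd.DataFrame(
        [
            {
                "population_id": p.population_id,
                "species": p.species,
                "latitude": p.latitude,
                "longitude": p.longitude,
            }
            for p in populations
        ]
    ).to_csv(path, index=False)


def read_climate_csv(
    path, variable_name: str, months=frozenset({2, 3, 4, 5}), max_missing_frac: float = 0.10
) -> ClimatePanel:
    """Read a climate CSV into a panel of annual seasonal-window means.

    Daily layout (population_id, date, value) is aggregated through
    :func:`~traitsync.preprocess.seasonal_mean`; annual layout
    (population_id, year, value) is used as-is.
    """
    df = pd.read_csv(path, dtype={"population_id": str})
    if {"population_id", "date", "value"}.issubset(df.columns):
        rows = []
        for pop, group in df.groupby("population_id"):
            series = seasonal_mean(
                list(zip(group["date"], group["value"])), months, max_missing_frac
            )
            for year, value in series.items():
                rows.append((pop, int(year), float(value)))
        long_df = pd.DataFrame(rows, columns=["population_id", "year", "value"])
    elif {"population_id", "year", "value"}.issubset(df.columns):
        long_df = df[["population_id", "year", "value"]]
    else:
        raise ValidationError(
            f"climate CSV {path}: expected (population_id, date, value) or "
            "(population_id, year, value)"
        )
    panel = Panel.from_long(long_df, variable_name)
    return ClimatePanel(panel.name, panel.populations, panel.years, panel.values, panel.mask)


def read_panel_csv(path, name: str) -> TraitPanel:
    """Read a long-format panel CSV (population_id, year, value)."""
    df = pd.read_csv(path, dtype={"population_id": str})
    panel = Panel.from_long(df, name)
    return TraitPanel(panel.name, panel.populations, panel.years, panel.values, panel.mask)


def write_panel_csv(panel: Panel, path) -> None:
    panel.to_long().to_csv(path, index=False)


def write_fit_json(
    fit: SynchronyFit, path, *, trait: str, species: str, n_populations: int, n_years: int
) -> None:
    report = {
        "trait": trait,
        "species": species,
        "n_populations": n_populations,
        "n_years": n_years,
        **fit.to_dict(),
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())
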