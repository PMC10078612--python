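"""End-to-end orchestration: brood table in, synchrony reports out.

For every species x trait cell the pipeline filters broods, aggregates to
annual averages, applies the long-term-study inclusion rule, detrends and
normalizes, fits the synchrony model with a parametric bootstrap, and
writes a fit report, correlogram band, and pairwise-correlation table.
With climate inputs configured it additionally fits the climate-adjusted
synchrony per climate variable.  A failing cell is logged and skipped;
other cells continue.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .climate import compare_synchrony
from .errors import TraitSyncError, ValidationError
from .io import (
    broods_from_frame,
    read_broods_csv,
    read_climate_csv,
    read_sites_csv,
    write_fit_json,
    write_panel_csv,
)
from .panels import TRAIT_NAMES, align_panels, require_min_years
from .preprocess import FilterRules, annual_average, detrend_normalize, filter_broods
from .plots import plot_comparison, plot_correlogram
from .synchrony import (
    DistanceMatrix,
    FitOptions,
    correlogram_band,
    fit_with_bootstrap,
    pairwise_empirical_correlations,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run (YAML-loadable)."""

    broods_path: str
    sites_path: str
    out_dir: str
    climate_paths: dict[str, str] = field(default_factory=dict)  # variable -> csv path
    traits: list[str] = field(default_factory=lambda: ["laying_date"])
    species: list[str] | None = None
    min_years: int = 9
    min_broods_per_year: int = 2
    fledgling_min: int = 1
    climate_months: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    climate_include_year: bool = False
    min_latitude: float | None = None
    n_starts: int = 10
    bootstrap_reps: int = 2000
    refit_starts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")
        if self.min_years < 3:
            raise ValidationError("min_years must be >= 3")
        unknown = set(self.traits) - set(TRAIT_NAMES)
        if unknown:
            raise ValidationError(f"unknown traits {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_canonical_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        return json.dumps(d, sort_keys=True, default=str)


def _cell_seed(master_seed: int, species: str, trait: str, variable: str = "") -> int:
    """Stable per-cell child seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}|{species}|{trait}|{variable}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def run_pipeline(config: PipelineConfig) -> int:
    """Run every species x trait cell; returns 0 ok, 1 all failed, 2 partial."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    broods_df = read_broods_csv(config.broods_path)
    sites = read_sites_csv(config.sites_path)
    site_by_id = {p.population_id: p for p in sites}
    species_list = config.species or sorted(broods_df["species"].unique())
    climate_panels = {
        var: read_climate_csv(path, var, frozenset(config.climate_months))
        for var, path in config.climate_paths.items()
    }
    fit_options = FitOptions(n_starts=config.n_starts)

    statuses: dict[str, str] = {}
    n_ok = n_fail = 0
    for species in species_list:
        sp_df = broods_df[broods_df["species"] == species]
        records = broods_from_frame(sp_df)
        for trait in config.traits:
            cell = f"{species}.{trait}"
            t0 = time.monotonic()
            try:
                _run_cell(
                    config, species, trait, records, site_by_id, climate_panels, fit_options, out
                )
                statuses[cell] = "ok"
                n_ok += 1
                logger.info(
                    "stage=cell species=%s trait=%s status=ok elapsed=%.1fs",
                    species, trait, time.monotonic() - t0,
                )
            except TraitSyncError as exc:
                statuses[cell] = f"failed: {exc}"
                n_fail += 1
                logger.error(
                    "stage=cell species=%s trait=%s status=failed elapsed=%.1fs error=%s",
                    species, trait, time.monotonic() - t0, exc,
                )

    manifest = {
        "config_sha256": hashlib.sha256(config.to_canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "traitsync_version": __version__,
        "numpy_version": np.__version__,
        "cells": statuses,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if n_ok == 0:
        return 1
    return 0 if n_fail == 0 else 2


def _run_cell(config, species, trait, records, site_by_id, climate_panels, fit_options, out):
    rules = FilterRules(
        trait,
        min_broods_per_year=config.min_broods_per_year,
        fledgling_min=config.fledgling_min,
    )
    filtered = filter_broods(records, rules)
    if not filtered:
        raise ValidationError(f"no broods left after filtering for {species}/{trait}")
    panel = annual_average(filtered, trait)
    panel = require_min_years(panel, config.min_years)
    if config.min_latitude is not None:
        keep = [
            p for p in panel.populations
            if p in site_by_id and site_by_id[p].latitude >= config.min_latitude
        ]
        if not keep:
            raise ValidationError(f"no populations above latitude {config.min_latitude}")
        panel = panel.subset_populations(keep)
    missing_sites = [p for p in panel.populations if p not in site_by_id]
    if missing_sites:
        raise ValidationError(f"populations without site coordinates: {missing_sites}")

    prefix = out / f"{species}_{trait}"
    write_panel_csv(panel, f"{prefix}_panel.csv")
    detrended = detrend_normalize(panel)
    write_panel_csv(detrended, f"{prefix}_detrended.csv")

    D = DistanceMatrix.from_populations([site_by_id[p] for p in panel.populations])
    fit = fit_with_bootstrap(
        detrended,
        D,
        config.bootstrap_reps,
        _cell_seed(config.seed, species, trait),
        fit_options,
        config.refit_starts,
    )
    write_fit_json(
        fit,
        f"{prefix}_fit.json",
        trait=trait,
        species=species,
        n_populations=detrended.n_populations,
        n_years=detrended.n_years,
    )
    grid = np.linspace(0.0, D.max_distance, 101)
    correlogram_band(fit.replicates, grid).to_csv(f"{prefix}_correlogram.csv", index=False)
    pairs = pairwise_empirical_correlations(detrended, D)
    pairs.to_csv(f"{prefix}_pairs.csv", index=False)
    plot_correlogram(
        fit, D.max_distance, pairs, title=f"{species} {trait}", path=f"{prefix}_correlogram.png"
    )

    for var, climate in climate_panels.items():
        p_aligned, c_aligned = align_panels(panel, climate)
        comparison = compare_synchrony(
            p_aligned,
            c_aligned,
            D.subset(p_aligned.populations),
            config.bootstrap_reps,
            _cell_seed(config.seed, species, trait, var),
            fit_options,
            include_year=config.climate_include_year,
            refit_starts=config.refit_starts,
        )
        Path(f"{prefix}_{var}_comparison.json").write_text(
            json.dumps(comparison.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        plot_comparison(
            comparison, title=f"{species} {trait} vs {var}", path=f"{prefix}_{var}_comparison.png"
        )
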