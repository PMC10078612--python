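"""Correlogram figures: fitted synchrony curves with bootstrap bands."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .climate import SynchronyComparison
from .synchrony import SynchronyFit, correlogram_band


def plot_correlogram(
    fit: SynchronyFit,
    max_distance: float,
    pairs: pd.DataFrame | None = None,
    title: str = "",
    path=None,
):
    """Fitted correlogram (bootstrap median and 95% band) over distance.

    Optionally overlays empirical pairwise correlations, with point size
    proportional to the number of overlapping years.
    """
    grid = np.linspace(0.0, max_distance, 200)
    band = correlogram_band(fit.replicates, grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    if pairs is not None and len(pairs):
        ax.scatter(
            pairs["distance_km"],
            pairs["pearson_r"],
            s=4 + 1.2 * pairs["n_overlap"],
            color="0.6",
            alpha=0.5,
            linewidths=0,
        )
    ax.fill_between(band["distance_km"], band["ci_low"], band["ci_high"], alpha=0.25)
    ax.plot(band["distance_km"], band["fitted_correlation_median"], lw=2)
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.set_xlabel("Distance (km)")
    ax.set_ylabel("Correlation")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_comparison(comparison: SynchronyComparison, title: str = "", path=None):
    """Raw vs climate-adjusted correlograms with bootstrap bands."""
    grid = comparison.distance_grid
    fig, ax = plt.subplots(figsize=(6, 4))
    for fit, label, style in (
        (comparison.raw_fit, "raw", "--"),
        (comparison.adjusted_fit, f"adjusted ({comparison.climate_variable})", "-"),
    ):
        band = correlogram_band(fit.replicates, grid)
        ax.fill_between(band["distance_km"], band["ci_low"], band["ci_high"], alpha=0.2)
        ax.plot(band["distance_km"], band["fitted_correlation_median"], style, lw=2, label=label)
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.set_xlabel("Distance (km)")
    ax.set_ylabel("Correlation")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
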