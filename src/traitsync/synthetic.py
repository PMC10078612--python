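"""Synthetic study generator with known synchrony structure.

Emulates the structure of a multi-site nest-box monitoring study — tens of
populations spread over hundreds to thousands of kilometres, decades of
partly overlapping annual coverage, per-population linear trends — with
annual average trait values drawn from the Gaussian-correlogram MVN model,
optionally driven by a spatially autocorrelated climate field.  Every
dataset carries its generating truth, so each pipeline stage can be tested
against known parameters without any download.

Defaults describe a laying-date-like trait: population mean near day 22
(1 = April 1), between-year SD about 5 days, and an advancing trend of
-0.17 days per year, matching the magnitudes seen in long-term European
tit monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .panels import ClimatePanel, TraitPanel
from .preprocess import BroodRecord, Population
from .synchrony import DistanceMatrix, SynchronyParams, build_sigma

_KM_PER_DEG_LAT = 111.19492664455873  # 6371 km * pi / 180


@dataclass(frozen=True)
class GeoBox:
    """A latitude/longitude bounding box (degrees); distances are haversine."""

    lat: tuple[float, float]
    lon: tuple[float, float]


@dataclass(frozen=True)
class ClimateDriver:
    """Spatially autocorrelated climate field with population-specific slopes.

    The observable trait field becomes beta * C + trait_sd * e where C and e
    are independent MVN fields with correlograms ``truth_c`` and
    ``noise_truth``.
    """

    truth_c: SynchronyParams
    beta: float | np.ndarray
    noise_truth: SynchronyParams


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic dataset.

    ``trend_per_year``, ``trait_sd``, and the climate driver's ``beta``
    accept either a scalar (shared by all sites) or a per-site array.
    ``block_missing`` maps population index to an observed (first_year,
    last_year) window, emulating studies that started and ended at
    different times; ``missing_rate`` thins the remaining observations
    independently.
    """

    n_sites: int = 30
    region: tuple[float, float] | GeoBox = (2000.0, 2000.0)
    n_years: int = 40
    truth: SynchronyParams = field(default_factory=lambda: SynchronyParams(0.7, 0.1, 500.0))
    mean: float = 22.0
    trend_per_year: float | np.ndarray = -0.17
    trait_sd: float | np.ndarray = 5.0
    missing_rate: float = 0.0
    block_missing: dict[int, tuple[int, int]] | None = None
    climate: ClimateDriver | None = None
    ar1: float = 0.0
    start_year: int = 1980
    trait_name: str = "laying_date"
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValidationError("n_sites must be >= 2")
        if self.n_years < 2:
            raise ValidationError("n_years must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not -1.0 < self.ar1 < 1.0:
            raise ValidationError("ar1 must be in (-1, 1)")
        if np.any(np.asarray(self.trait_sd) <= 0):
            raise ValidationError("trait_sd must be positive")


def generate_sites(
    n: int, region: tuple[float, float] | GeoBox, seed: int
) -> tuple[list[Population], DistanceMatrix]:
    """Place ``n`` sites uniformly at random in the region.

    Planar regions (width, height in km) use Euclidean distances; the
    returned coordinates are a local chart around 50 deg N, 10 deg E and
    are synthetic.  Lat/lon boxes use haversine distances.  Deterministic
    given ``seed``.
    """
    if n < 2:
        raise ValidationError("need n >= 2 sites")
    rng = np.random.default_rng(seed)
    if isinstance(region, GeoBox):
        (lat0, lat1), (lon0, lon1) = region.lat, region.lon
        if lat0 >= lat1 or lon0 >= lon1:
            raise ValidationError("degenerate lat/lon box")
        lat = rng.uniform(lat0, lat1, n)
        lon = rng.uniform(lon0, lon1, n)
        pops = [
            Population(f"site{i:03d}", "synthetic", float(lat[i]), float(lon[i]))
            for i in range(n)
        ]
        return pops, DistanceMatrix.from_populations(pops)
    width, height = float(region[0]), float(region[1])
    if width < 0 or height < 0 or (width == 0 and height == 0):
        raise ValidationError("degenerate planar region")
    x = rng.uniform(0.0, width, n)
    y = rng.uniform(0.0, height, n)
    d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    # chart coordinates for bookkeeping only; distances above are authoritative
    lat = 50.0 + (y - y.mean()) / _KM_PER_DEG_LAT
    lon = 10.0 + (x - x.mean()) / (_KM_PER_DEG_LAT * np.cos(np.radians(50.0)))
    pops = [
        Population(f"site{i:03d}", "synthetic", float(lat[i]), float(lon[i])) for i in range(n)
    ]
    return pops, DistanceMatrix([p.population_id for p in pops], d)


@dataclass
class SimulatedStudy:
    """A generated dataset together with its generating truth."""

    scenario: SimulationScenario
    populations: list[Population]
    distances: DistanceMatrix
    raw: TraitPanel
    latent: TraitPanel
    climate: ClimatePanel | None


def _draw_field(
    sigma_chol: np.ndarray,
    n_years: int,
    rng: np.random.Generator,
    ar1: float = 0.0,
) -> np.ndarray:
    """(n_sites, n_years) matrix of MVN(0, Sigma) columns.

    Years are i.i.d. by default (the model's assumption after detrending);
    a nonzero ``ar1`` applies a stationary AR(1) recursion over years,
    preserving the marginal covariance, to stress-test robustness to
    temporal autocorrelation.
    """
    z = sigma_chol @ rng.standard_normal((sigma_chol.shape[0], n_years))
    if ar1 != 0.0:
        scale = np.sqrt(1.0 - ar1**2)
        for t in range(1, n_years):
            z[:, t] = ar1 * z[:, t - 1] + scale * z[:, t]
    return z


def _chol(p: SynchronyParams, D: DistanceMatrix) -> np.ndarray:
    sigma = build_sigma(p, D)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        # singular PSD case (e.g. perfect synchrony): exact square root via eigh
        w, v = np.linalg.eigh(sigma)
        return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_study(scenario: SimulationScenario) -> SimulatedStudy:
    """Generate sites, latent synchronous field, observable panel, and climate.

    The latent field is always complete (no missingness) and standardized,
    enabling exact oracle comparisons; missingness is applied to the
    observable raw panel only.  With a climate driver configured, the
    observable field is beta * C + trait_sd * e and the returned latent
    panel is the residual noise field e — the synchrony that should remain
    after a perfect climate adjustment.
    """
    ss = np.random.SeedSequence(scenario.seed)
    s_sites, s_field, s_climate, s_miss = ss.spawn(4)
    pops, D = generate_sites(scenario.n_sites, scenario.region, s_sites)
    n, T = scenario.n_sites, scenario.n_years
    years = list(range(scenario.start_year, scenario.start_year + T))
    yr = np.asarray(years, dtype=float)
    dy = yr - yr.mean()

    rng_field = np.random.default_rng(s_field)
    trend = np.broadcast_to(np.asarray(scenario.trend_per_year, dtype=float), (n,))
    sd = np.broadcast_to(np.asarray(scenario.trait_sd, dtype=float), (n,))
    deterministic = scenario.mean + trend[:, None] * dy[None, :]

    climate_panel = None
    pop_ids = [p.population_id for p in pops]
    if scenario.climate is None:
        z = _draw_field(_chol(scenario.truth, D), T, rng_field, scenario.ar1)
        raw_values = deterministic + sd[:, None] * z
        latent = z
    else:
        drv = scenario.climate
        rng_climate = np.random.default_rng(s_climate)
        C = _draw_field(_chol(drv.truth_c, D), T, rng_climate, scenario.ar1)
        e = _draw_field(_chol(drv.noise_truth, D), T, rng_field, scenario.ar1)
        beta = np.broadcast_to(np.asarray(drv.beta, dtype=float), (n,))
        raw_values = deterministic + beta[:, None] * C + sd[:, None] * e
        latent = e
        climate_panel = ClimatePanel(
            name="synthetic_climate",
            populations=pop_ids,
            years=years,
            values=C,
            mask=np.ones((n, T), dtype=bool),
        )

    mask = np.ones((n, T), dtype=bool)
    if scenario.block_missing:
        for i, (first, last) in scenario.block_missing.items():
            mask[i] &= (yr >= first) & (yr <= last)
    if scenario.missing_rate > 0:
        rng_miss = np.random.default_rng(s_miss)
        mask &= rng_miss.random((n, T)) >= scenario.missing_rate
    if (mask.sum(axis=0) >= 2).sum() < 2 or (mask.sum(axis=1) >= 2).sum() < 2:
        raise ValidationError("missingness pattern leaves fewer than 2 sites in 2 years")

    raw = TraitPanel(
        name=scenario.trait_name,
        populations=pop_ids,
        years=years,
        values=np.where(mask, raw_values, np.nan),
        mask=mask,
    )
    latent_panel = TraitPanel(
        name=f"{scenario.trait_name}_latent",
        populations=pop_ids,
        years=years,
        values=latent,
        mask=np.ones((n, T), dtype=bool),
    )
    return SimulatedStudy(scenario, pops, D, raw, latent_panel, climate_panel)


def generate_panel(
    scenario: SimulationScenario,
) -> tuple[TraitPanel, TraitPanel, ClimatePanel | None]:
    """(observable raw panel, complete latent panel, optional climate panel)."""
    study = simulate_study(scenario)
    return study.raw, study.latent, study.climate


def emit_brood_table(
    panel: TraitPanel,
    broods_per_year: int = 10,
    within_year_sd: float = 3.0,
    seed: int = 0,
) -> list[BroodRecord]:
    """Minimal brood-table emitter around a panel's annual values.

    Scatters ``broods_per_year`` first-clutch, non-experimental broods
    around each observed annual value so the brood-level filters and
    aggregation can be exercised.  Laying-date panels fill the laying_date
    field; clutch-size panels fill clutch_size (and a fledgling count drawn
    below it).  This is not an individual-level model of real brood data
    (no right-skewed laying distributions, no experiments).
    """
    rng = np.random.default_rng(seed)
    records = []
    for i, pop in enumerate(panel.populations):
        for j, year in enumerate(panel.years):
            if not panel.mask[i, j]:
                continue
            center = panel.values[i, j]
            for _ in range(broods_per_year):
                if panel.trait_name == "clutch_size":
                    clutch = max(1, int(round(rng.normal(center, within_year_sd))))
                    fledged = int(rng.integers(0, clutch + 1))
                    records.append(
                        BroodRecord(pop, int(year), clutch_size=clutch, fledgling_number=fledged)
                    )
                else:
                    ld = int(round(rng.normal(center, within_year_sd)))
                    clutch = max(1, int(round(rng.normal(9.0, 1.5))))
                    fledged = int(rng.integers(0, clutch + 1))
                    records.append(
                        BroodRecord(
                            pop,
                            int(year),
                            laying_date=ld,
                            clutch_size=clutch,
                            fledgling_number=fledged,
                        )
                    )
    return records
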