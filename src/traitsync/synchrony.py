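"""Parametric spatial-synchrony estimation.

The model: detrended, normalized annual trait values of the populations
observed in year t follow a zero-mean multivariate normal with unit
diagonal and pairwise correlation decaying with distance as a Gaussian
correlogram,

    rho(d) = rho_inf + (rho0 - rho_inf) * exp(-d^2 / (2 l^2)),

where ``rho0`` is the correlation as distance approaches zero (1 - rho0 is
a nugget of purely local variability), ``rho_inf`` the distance-independent
regional floor, and ``l`` (km) the standard deviation of the Gaussian decay
kernel — the characteristic distance over which fluctuations remain
correlated.  Because site coverage differs among years, each year
contributes the MVN log-density of the populations available that year; the
total log-likelihood is the sum over years, maximized numerically under the
constraint 0 <= rho_inf <= rho0 <= 1.  Uncertainty comes from a parametric
bootstrap: simulate panels from the fitted model on the observed
availability pattern, refit each, and report percentile intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc

from .errors import BootstrapQualityError, OptimizationError, ValidationError
from .panels import Panel, TraitPanel
from .preprocess import Population

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

_PARAM_NAMES = ("rho0", "rho_inf", "l")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points, Earth radius 6371 km."""
    for lat, lon in (a, b):
        if not -90.0 <= lat <= 90.0:
            raise ValidationError(f"latitude {lat} out of [-90, 90]")
        if not -180.0 <= lon <= 180.0:
            raise ValidationError(f"longitude {lon} out of [-180, 180]")
    phi1, phi2 = np.radians(a[0]), np.radians(b[0])
    dphi = phi2 - phi1
    dlmb = np.radians(b[1] - a[1])
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of inter-population distances in kilometers."""

    populations: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.populations = [str(p) for p in self.populations]
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.populations)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if np.any(self.d < 0):
            raise ValidationError("negative distance")
        if np.any(np.abs(np.diag(self.d)) > 1e-9):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.max(np.abs(self.d - self.d.T)) > 1e-9:
            raise ValidationError("distance matrix must be symmetric")
        self.d = 0.5 * (self.d + self.d.T)

    @classmethod
    def from_populations(cls, populations: list[Population]) -> "DistanceMatrix":
        """Haversine distances between population coordinates."""
        n = len(populations)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = haversine_km(
                    (populations[i].latitude, populations[i].longitude),
                    (populations[j].latitude, populations[j].longitude),
                )
        return cls([p.population_id for p in populations], d)

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.populations.index(p) for p in keep]
        return DistanceMatrix(list(keep), self.d[np.ix_(idx, idx)].copy())

    @property
    def max_distance(self) -> float:
        return float(self.d.max())


@dataclass(frozen=True)
class SynchronyParams:
    """Gaussian-correlogram parameters (rho0, rho_inf, l).

    ``rho0``: correlation at zero distance; ``rho_inf``: correlation at
    infinite distance; ``l``: spatial scale in km.  The admissible space is
    0 <= rho_inf <= rho0 <= 1, l > 0 (the model is restricted to positive
    correlations).
    """

    rho0: float
    rho_inf: float
    l: float

    def __post_init__(self):
        if not 0.0 <= self.rho0 <= 1.0:
            raise ValidationError(f"rho0 {self.rho0} outside [0, 1]")
        if not 0.0 <= self.rho_inf <= self.rho0 + 1e-12:
            raise ValidationError(f"rho_inf {self.rho_inf} outside [0, rho0={self.rho0}]")
        if not self.l > 0.0:
            raise ValidationError(f"spatial scale l {self.l} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.rho0, self.rho_inf, self.l])

    @classmethod
    def from_array(cls, x) -> "SynchronyParams":
        return cls(float(x[0]), float(min(x[1], x[0])), float(x[2]))


def correlation_at_distance(p: SynchronyParams, d) -> float | np.ndarray:
    """Evaluate the Gaussian correlogram rho(d) at distance(s) d (km)."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValidationError("distance must be non-negative")
    out = p.rho_inf + (p.rho0 - p.rho_inf) * np.exp(-(d_arr**2) / (2.0 * p.l**2))
    return float(out) if np.isscalar(d) or d_arr.ndim == 0 else out


def build_sigma(p: SynchronyParams, D: DistanceMatrix) -> np.ndarray:
    """Model correlation matrix: unit diagonal, Gaussian-correlogram off-diagonals.

    Positive semidefinite for every valid parameter set because it
    decomposes as rho_inf * J + (rho0 - rho_inf) * Gaussian kernel +
    (1 - rho0) * I.
    """
    sigma = p.rho_inf + (p.rho0 - p.rho_inf) * np.exp(-(D.d**2) / (2.0 * p.l**2))
    np.fill_diagonal(sigma, 1.0)
    return sigma


# --------------------------------------------------------------------------
# Likelihood
# --------------------------------------------------------------------------

_LOG_2PI = float(np.log(2.0 * np.pi))


class PanelLikelihood:
    """Precomputed total log-likelihood of a panel under the synchrony model.

    Years are grouped by availability pattern so the Cholesky factorization
    of each distinct sub-correlation-matrix is computed once per parameter
    evaluation.  Years with a single available population contribute their
    parameter-free univariate standard-normal terms (the diagonal is 1), so
    log-likelihoods remain comparable across parameter sets; empty years are
    skipped.
    """

    def __init__(self, panel: Panel, D: DistanceMatrix, ridge: float = 1e-8):
        if panel.populations != D.populations:
            raise ValidationError(
                "panel and distance-matrix population orders are not aligned"
            )
        self.D = D
        self.ridge = ridge
        self.n_populations = panel.n_populations
        # constant contribution of single-population years
        self._const = 0.0
        self._groups: list[tuple[np.ndarray, np.ndarray]] = []  # (pop indices, Y (k, m))
        patterns: dict[bytes, list[int]] = {}
        for t in range(panel.n_years):
            col = panel.mask[:, t]
            k = int(col.sum())
            if k == 0:
                continue
            if k == 1:
                y = float(panel.values[col, t][0])
                self._const += -0.5 * (_LOG_2PI + y * y)
                continue
            patterns.setdefault(col.tobytes(), []).append(t)
        for key, ts in patterns.items():
            col = np.frombuffer(key, dtype=bool)
            idx = np.flatnonzero(col)
            Y = panel.values[np.ix_(idx, ts)]  # shape (k, m)
            self._groups.append((idx, Y))
        self.n_informative_years = sum(Y.shape[1] for _, Y in self._groups)

    def loglik(self, p: SynchronyParams) -> float:
        sigma = build_sigma(p, self.D)
        total = self._const
        for idx, Y in self._groups:
            sub = sigma[np.ix_(idx, idx)]
            k, m = Y.shape
            try:
                c, low = cho_factor(sub, lower=True, check_finite=False)
            except LinAlgError:
                logger.warning(
                    "singular correlation submatrix (k=%d); adding ridge %.1e", k, self.ridge
                )
                c, low = cho_factor(
                    sub + self.ridge * np.eye(k), lower=True, check_finite=False
                )
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            quad = float(np.sum(Y * cho_solve((c, low), Y, check_finite=False)))
            total += -0.5 * (m * k * _LOG_2PI + m * logdet + quad)
        return total


def total_loglik(p: SynchronyParams, panel: Panel, D: DistanceMatrix) -> float:
    """Sum of annual MVN log-densities of the panel under parameters ``p``."""
    return PanelLikelihood(panel, D).loglik(p)


# --------------------------------------------------------------------------
# Maximum-likelihood fit
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_synchrony`.

    The box constraint 0 <= rho_inf <= rho0 <= 1 is enforced by an internal
    unconstrained parameterization (logit for rho0, rho_inf = rho0 *
    inverse-logit(u), log for l); the likelihood surface can be multimodal,
    so the local quasi-Newton search is repeated from ``n_starts``
    space-filling start points (a Halton design over the box) and the best
    solution is returned.  ``l`` is bounded above by ``l_max_factor`` times
    the maximum pairwise distance: beyond that the data cannot distinguish a
    large scale from a flat correlogram.
    """

    n_starts: int = 10
    l_min_km: float = 1.0
    l_max_factor: float = 5.0
    ridge: float = 1e-8
    maxiter: int = 300

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")


_U_BOUNDS = [(-9.0, 9.0), (-30.0, 9.0), None]  # third bound set per dataset


def _to_params(u: np.ndarray) -> SynchronyParams:
    rho0 = float(expit(u[0]))
    rho_inf = rho0 * float(expit(u[1]))
    return SynchronyParams(rho0, rho_inf, float(np.exp(u[2])))


def _halton_starts(n: int, l_lo: float, l_hi: float) -> np.ndarray:
    """Deterministic space-filling start points in internal coordinates."""
    h = qmc.Halton(d=3, scramble=False)
    h.fast_forward(1)  # skip the origin
    x = h.random(n)
    u = np.empty_like(x)
    u[:, 0] = logit(0.10 + 0.85 * x[:, 0])  # rho0 in [0.10, 0.95]
    u[:, 1] = logit(0.02 + 0.85 * x[:, 1])  # rho_inf / rho0 in [0.02, 0.87]
    u[:, 2] = np.log(l_lo) + x[:, 2] * (np.log(l_hi) - np.log(l_lo))
    return u


def fit_synchrony(
    panel: Panel,
    D: DistanceMatrix,
    options: FitOptions | None = None,
    extra_starts: list[SynchronyParams] | None = None,
) -> tuple[SynchronyParams, float]:
    """Constrained maximum-likelihood estimate of the synchrony parameters.

    Returns the best (parameters, log-likelihood) over all optimizer starts.
    Boundary estimates (e.g. rho_inf = 0) are legitimate outputs.
    ``extra_starts`` prepends warm starts (used by the bootstrap) to the
    space-filling design.
    """
    options = options or FitOptions()
    if panel.n_populations < 2:
        raise ValidationError("fit_synchrony requires >= 2 populations")
    lik = PanelLikelihood(panel, D, ridge=options.ridge)
    if lik.n_informative_years < 2:
        raise ValidationError("fit_synchrony requires >= 2 years with >= 2 available populations")

    l_max = options.l_max_factor * max(D.max_distance, options.l_min_km)
    l_lo = max(options.l_min_km, 0.02 * D.max_distance)
    l_hi = max(1.2 * D.max_distance, 2.0 * l_lo)
    bounds = [_U_BOUNDS[0], _U_BOUNDS[1], (np.log(options.l_min_km), np.log(l_max))]

    def objective(u: np.ndarray) -> float:
        try:
            val = -lik.loglik(_to_params(u))
        except (ValidationError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    starts = []
    for p in extra_starts or []:
        ratio = np.clip(p.rho_inf / max(p.rho0, 1e-9), 1e-9, 1 - 1e-9)
        starts.append(
            np.array(
                [
                    logit(np.clip(p.rho0, 1e-4, 1 - 1e-4)),
                    logit(ratio),
                    np.log(np.clip(p.l, options.l_min_km, l_max)),
                ]
            )
        )
    starts.extend(_halton_starts(options.n_starts, l_lo, l_hi))

    best = None
    diagnostics = []
    for u0 in starts:
        res = minimize(
            objective,
            u0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.maxiter},
        )
        diagnostics.append({"x0": u0, "fun": res.fun, "status": res.status})
        if np.isfinite(res.fun) and res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise OptimizationError("no optimizer start converged", diagnostics)
    return _to_params(best.x), float(-best.fun)


# --------------------------------------------------------------------------
# Parametric bootstrap
# --------------------------------------------------------------------------


@dataclass
class SynchronyFit:
    """Point estimate plus parametric-bootstrap uncertainty.

    ``replicates`` holds one (rho0, rho_inf, l) row per converged bootstrap
    replicate; ``median`` and ``ci95`` are percentile summaries over those
    rows (the headline estimate reported for a trait is the bootstrap
    median).
    """

    point: SynchronyParams
    loglik: float
    replicates: np.ndarray
    median: SynchronyParams
    ci95: dict[str, tuple[float, float]]
    n_replicates_requested: int
    n_replicates_converged: int

    def to_dict(self) -> dict:
        return {
            "point": {"rho0": self.point.rho0, "rho_inf": self.point.rho_inf, "l_km": self.point.l},
            "loglik": self.loglik,
            "bootstrap": {
                "B": self.n_replicates_requested,
                "converged": self.n_replicates_converged,
                "median": {
                    "rho0": self.median.rho0,
                    "rho_inf": self.median.rho_inf,
                    "l_km": self.median.l,
                },
                "ci95": {k: list(v) for k, v in self.ci95.items()},
            },
        }


def _summarize_replicates(
    point: SynchronyParams, loglik: float, reps: np.ndarray, requested: int
) -> SynchronyFit:
    med = np.median(reps, axis=0)
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    return SynchronyFit(
        point=point,
        loglik=loglik,
        replicates=reps,
        median=SynchronyParams.from_array(med),
        ci95={name: (float(lo[i]), float(hi[i])) for i, name in enumerate(_PARAM_NAMES)},
        n_replicates_requested=requested,
        n_replicates_converged=reps.shape[0],
    )


def simulate_panel(
    p: SynchronyParams,
    mask: np.ndarray,
    D: DistanceMatrix,
    rng: np.random.Generator,
    years: list[int] | None = None,
    name: str = "simulated",
) -> TraitPanel:
    """Draw one panel from the synchrony model on a given availability pattern.

    Each year's vector is an independent draw from MVN(0, Sigma) restricted
    to the populations available that year.
    """
    mask = np.asarray(mask, dtype=bool)
    n_pop, n_years = mask.shape
    if n_pop != len(D.populations):
        raise ValidationError("mask row count does not match distance matrix")
    sigma = build_sigma(p, D)
    chols: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    values = np.full(mask.shape, np.nan)
    for t in range(n_years):
        col = mask[:, t]
        k = int(col.sum())
        if k == 0:
            continue
        key = col.tobytes()
        if key not in chols:
            idx = np.flatnonzero(col)
            sub = sigma[np.ix_(idx, idx)]
            try:
                chol = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                chol = np.linalg.cholesky(sub + 1e-8 * np.eye(k))
            chols[key] = (idx, chol)
        idx, chol = chols[key]
        values[idx, t] = chol @ rng.standard_normal(k)
    return TraitPanel(
        name=name,
        populations=list(D.populations),
        years=list(years) if years is not None else list(range(n_years)),
        values=values,
        mask=mask.copy(),
    )


def parametric_bootstrap(
    point: SynchronyParams,
    mask: np.ndarray,
    D: DistanceMatrix,
    B: int,
    seed: int,
    loglik: float = float("nan"),
    options: FitOptions | None = None,
    refit_starts: int = 3,
    max_failure_frac: float = 0.2,
) -> SynchronyFit:
    """Parametric-bootstrap distribution of the synchrony parameters.

    For each of ``B`` replicates, a panel is simulated from the fitted model
    on the observed availability pattern and refitted.  Refits warm-start at
    the point estimate plus ``refit_starts`` space-filling starts.
    Non-converging replicates are dropped and counted; more than
    ``max_failure_frac`` failures raises :class:`BootstrapQualityError`.
    Deterministic given ``seed``.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    options = options or FitOptions()
    refit_options = FitOptions(
        n_starts=refit_starts,
        l_min_km=options.l_min_km,
        l_max_factor=options.l_max_factor,
        ridge=options.ridge,
        maxiter=options.maxiter,
    )
    rows = []
    n_failed = 0
    for child in np.random.SeedSequence(seed).spawn(B):
        rng = np.random.default_rng(child)
        sim = simulate_panel(point, mask, D, rng)
        try:
            est, _ = fit_synchrony(sim, D, refit_options, extra_starts=[point])
        except OptimizationError:
            n_failed += 1
            continue
        rows.append(est.as_array())
    if n_failed > max_failure_frac * B:
        raise BootstrapQualityError(
            f"{n_failed}/{B} bootstrap replicates failed to converge "
            f"(> {max_failure_frac:.0%} allowed)"
        )
    if n_failed:
        logger.warning("dropped %d/%d non-converged bootstrap replicates", n_failed, B)
    reps = np.asarray(rows)
    return _summarize_replicates(point, loglik, reps, B)


def fit_with_bootstrap(
    panel: Panel,
    D: DistanceMatrix,
    B: int,
    seed: int,
    options: FitOptions | None = None,
    refit_starts: int = 3,
) -> SynchronyFit:
    """Convenience: maximum-likelihood fit followed by parametric bootstrap."""
    point, ll = fit_synchrony(panel, D, options)
    return parametric_bootstrap(
        point, panel.mask, D, B, seed, loglik=ll, options=options, refit_starts=refit_starts
    )


# --------------------------------------------------------------------------
# Empirical correlogram
# --------------------------------------------------------------------------


def pairwise_empirical_correlations(
    panel: Panel, D: DistanceMatrix, min_overlap: int = 5
) -> pd.DataFrame:
    """Pearson correlation per population pair over their overlapping years.

    Returns a frame with columns pop_a, pop_b, distance_km, pearson_r,
    n_overlap; pairs with fewer than ``min_overlap`` shared observed years,
    or with a zero-variance overlap series, are omitted.
    """
    if min_overlap < 3:
        raise ValidationError("min_overlap must be >= 3")
    if panel.populations != D.populations:
        raise ValidationError("panel and distance-matrix population orders are not aligned")
    rows = []
    n = panel.n_populations
    for i in range(n):
        for j in range(i + 1, n):
            both = panel.mask[i] & panel.mask[j]
            m = int(both.sum())
            if m < min_overlap:
                continue
            a, b = panel.values[i, both], panel.values[j, both]
            if a.std() == 0.0 or b.std() == 0.0:
                logger.warning(
                    "skipping pair (%s, %s): zero-variance overlap series",
                    panel.populations[i],
                    panel.populations[j],
                )
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            rows.append((panel.populations[i], panel.populations[j], float(D.d[i, j]), r, m))
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "distance_km", "pearson_r", "n_overlap"])


def correlogram_band(
    replicates: np.ndarray, distances: np.ndarray
) -> pd.DataFrame:
    """Median and 95% band of the fitted correlogram on a distance grid.

    Evaluates rho(d) for every bootstrap replicate's parameters and
    summarizes pointwise.
    """
    distances = np.asarray(distances, dtype=float)
    curves = np.empty((replicates.shape[0], distances.size))
    for r, row in enumerate(replicates):
        curves[r] = correlation_at_distance(SynchronyParams.from_array(row), distances)
    return pd.DataFrame(
        {
            "distance_km": distances,
            "fitted_correlation_median": np.median(curves, axis=0),
            "ci_low": np.percentile(curves, 2.5, axis=0),
            "ci_high": np.percentile(curves, 97.5, axis=0),
        }
    )
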