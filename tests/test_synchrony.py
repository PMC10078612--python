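"""Correlogram, MVN likelihood, constrained ML fit, and parametric bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from traitsync import (
    DistanceMatrix,
    FitOptions,
    SynchronyParams,
    ValidationError,
    build_sigma,
    correlation_at_distance,
    fit_synchrony,
    haversine_km,
    pairwise_empirical_correlations,
    parametric_bootstrap,
    simulate_panel,
    total_loglik,
)
from traitsync.synchrony import PanelLikelihood
from .conftest import make_panel

DEG_KM = 6371.0 * np.pi / 180.0


def valid_params(draw_rho0, draw_ratio, draw_l):
    rho0 = draw_rho0
    return SynchronyParams(rho0, rho0 * draw_ratio, draw_l)


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km((50.0, 5.0), (50.0, 5.0)) == 0.0

    def test_one_degree_meridian_arc(self):
        assert haversine_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(DEG_KM, abs=1e-4)

    def test_antipodal_half_circumference(self):
        assert haversine_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(
            np.pi * 6371.0, abs=1e-2
        )

    def test_symmetry(self):
        a, b = (52.3, 4.9), (63.4, 10.4)
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a), abs=1e-12)

    def test_out_of_range_coordinates(self):
        with pytest.raises(ValidationError):
            haversine_km((95.0, 0.0), (0.0, 0.0))


class TestCorrelogram:
    def test_table_values_at_zero_limit_and_scale(self):
        p = SynchronyParams(0.800, 0.263, 247.0)
        assert correlation_at_distance(p, 0.0) == pytest.approx(0.800)
        assert correlation_at_distance(p, 1e9) == pytest.approx(0.263, abs=1e-12)
        assert correlation_at_distance(p, 247.0) == pytest.approx(
            0.263 + 0.537 * np.exp(-0.5), abs=1e-12
        )
        assert correlation_at_distance(p, 247.0) == pytest.approx(0.58871, abs=1e-5)

    @settings(derandomize=True, max_examples=60)
    @given(
        rho0=st.floats(0.0, 1.0),
        ratio=st.floats(0.0, 1.0),
        l=st.floats(1.0, 5000.0),
    )
    def test_bounds_and_monotone_decay(self, rho0, ratio, l):
        p = SynchronyParams(rho0, rho0 * ratio, l)
        grid = np.linspace(0.0, 10000.0, 200)
        rho = correlation_at_distance(p, grid)
        assert np.all(rho <= p.rho0 + 1e-12) and np.all(rho >= p.rho_inf - 1e-12)
        assert np.all(np.diff(rho) <= 1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            correlation_at_distance(SynchronyParams(0.5, 0.1, 100.0), -1.0)

    def test_invalid_parameter_ordering_rejected(self):
        with pytest.raises(ValidationError):
            SynchronyParams(0.3, 0.5, 100.0)


class TestBuildSigma:
    def test_single_population(self):
        D = DistanceMatrix(["a"], [[0.0]])
        np.testing.assert_array_equal(
            build_sigma(SynchronyParams(0.9, 0.1, 50.0), D), [[1.0]]
        )

    def test_colocated_pair_keeps_nugget(self):
        D = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        sigma = build_sigma(SynchronyParams(0.8, 0.2, 100.0), D)
        assert sigma[0, 0] == 1.0 and sigma[0, 1] == pytest.approx(0.8)

    def test_random_layout_positive_semidefinite(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 2000, (25, 2))
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        sigma = build_sigma(
            SynchronyParams(0.9, 0.2, 300.0), DistanceMatrix([f"s{i}" for i in range(25)], d)
        )
        assert np.linalg.eigvalsh(sigma).min() >= -1e-10


class TestTotalLoglik:
    def test_closed_form_univariate(self, two_site_distance):
        D = DistanceMatrix(["a"], [[0.0]])
        panel = make_panel([[0.0]], populations=["a"])
        p = SynchronyParams(0.5, 0.1, 100.0)
        assert total_loglik(p, panel, D) == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-10)

    def test_closed_form_independent_pair(self):
        D = DistanceMatrix(["a", "b"], [[0.0, 1e9], [1e9, 0.0]])
        panel = make_panel([[0.0], [0.0]], populations=["a", "b"])
        p = SynchronyParams(0.5, 0.0, 100.0)
        assert total_loglik(p, panel, D) == pytest.approx(-np.log(2 * np.pi), abs=1e-10)

    def test_closed_form_correlated_pair(self):
        D = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        panel = make_panel([[1.0], [1.0]], populations=["a", "b"])
        p = SynchronyParams(0.5, 0.0, 100.0)
        expected = -np.log(2 * np.pi) - 0.5 * np.log(0.75) - 0.5 * (4.0 / 3.0)
        assert total_loglik(p, panel, D) == pytest.approx(expected, abs=1e-10)
        assert total_loglik(p, panel, D) == pytest.approx(-2.36071, abs=1e-5)

    def test_matches_dense_mvn_oracle_with_missing_years(self):
        rng = np.random.default_rng(11)
        n, T = 5, 8
        xy = rng.uniform(0, 1500, (n, 2))
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        D = DistanceMatrix([f"s{i}" for i in range(n)], d)
        p = SynchronyParams(0.75, 0.15, 400.0)
        values = rng.normal(size=(n, T))
        mask = rng.random((n, T)) < 0.7
        mask[:, 0] = True
        values = np.where(mask, values, np.nan)
        panel = make_panel(values, populations=D.populations)
        sigma = build_sigma(p, D)
        expected = 0.0
        for t in range(T):
            idx = np.flatnonzero(mask[:, t])
            if idx.size == 0:
                continue
            expected += multivariate_normal.logpdf(
                values[idx, t], mean=np.zeros(idx.size), cov=sigma[np.ix_(idx, idx)]
            )
        assert total_loglik(p, panel, D) == pytest.approx(expected, abs=1e-8)

    def test_permutation_invariance(self, small_study):
        p = SynchronyParams(0.6, 0.05, 600.0)
        panel, D = small_study.latent, small_study.distances
        base = total_loglik(p, panel, D)
        perm = np.random.default_rng(1).permutation(panel.n_populations)
        pops = [panel.populations[i] for i in perm]
        assert total_loglik(p, panel.subset_populations(pops), D.subset(pops)) == pytest.approx(
            base, rel=1e-12
        )

    def test_year_duplication_doubles_loglik(self, small_study):
        p = SynchronyParams(0.6, 0.05, 600.0)
        panel, D = small_study.latent, small_study.distances
        doubled = make_panel(
            np.hstack([panel.values, panel.values]),
            years=list(range(2 * panel.n_years)),
            populations=panel.populations,
        )
        assert total_loglik(p, doubled, D) == pytest.approx(
            2 * total_loglik(p, panel, D), rel=1e-12
        )

    def test_misaligned_populations_rejected(self, small_study):
        p = SynchronyParams(0.6, 0.05, 600.0)
        pops = list(reversed(small_study.latent.populations))
        with pytest.raises(ValidationError, match="aligned"):
            total_loglik(p, small_study.latent, small_study.distances.subset(pops))

    def test_single_population_years_contribute_constant(self):
        # a year with one available site adds its parameter-free N(0,1) term
        D = DistanceMatrix(["a", "b"], [[0.0, 200.0], [200.0, 0.0]])
        values = np.array([[0.5, 1.0], [0.2, np.nan]])
        panel = make_panel(values, populations=["a", "b"])
        p1, p2 = SynchronyParams(0.9, 0.0, 100.0), SynchronyParams(0.2, 0.0, 900.0)
        lik = PanelLikelihood(panel, D)
        solo = -0.5 * (np.log(2 * np.pi) + 1.0)
        both_years = lik.loglik(p1) - total_loglik(
            p1, make_panel(values[:, :1], populations=["a", "b"]), D
        )
        assert both_years == pytest.approx(solo, abs=1e-10)
        assert lik.loglik(p1) - lik.loglik(p2) == pytest.approx(
            total_loglik(p1, make_panel(values[:, :1], populations=["a", "b"]), D)
            - total_loglik(p2, make_panel(values[:, :1], populations=["a", "b"]), D),
            abs=1e-10,
        )


class TestFitSynchrony:
    def test_recovers_truth_roughly_on_one_simulation(self, small_study):
        est, ll = fit_synchrony(small_study.latent, small_study.distances)
        truth = small_study.scenario.truth
        assert abs(est.rho0 - truth.rho0) < 0.15
        assert abs(est.rho_inf - truth.rho_inf) < 0.15
        assert np.isfinite(ll)

    def test_iid_noise_gives_near_zero_synchrony(self):
        rng = np.random.default_rng(9)
        n = 15
        xy = rng.uniform(0, 3000, (n, 2))
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        D = DistanceMatrix([f"s{i}" for i in range(n)], d)
        values = rng.standard_normal((n, 40))
        panel = make_panel(values, years=list(range(40)), populations=D.populations)
        est, ll = fit_synchrony(panel, D)
        indep = -0.5 * (np.log(2 * np.pi) * values.size + (values**2).sum())
        assert est.rho0 < 0.15
        assert ll >= indep - 1e-6  # MLE dominates the independence model
        assert ll - indep < 10.0

    def test_permutation_invariance_of_estimate(self, small_study):
        panel, D = small_study.latent, small_study.distances
        est_a, ll_a = fit_synchrony(panel, D)
        perm = np.random.default_rng(2).permutation(panel.n_populations)
        pops = [panel.populations[i] for i in perm]
        est_b, ll_b = fit_synchrony(panel.subset_populations(pops), D.subset(pops))
        assert ll_a == pytest.approx(ll_b, abs=1e-4)
        assert est_a.rho0 == pytest.approx(est_b.rho0, abs=1e-4)

    def test_requires_two_populations(self):
        D = DistanceMatrix(["a"], [[0.0]])
        with pytest.raises(ValidationError):
            fit_synchrony(make_panel([[0.1, 0.2, 0.3]], populations=["a"]), D)


class TestParametricBootstrap:
    def test_single_replicate_median_is_that_replicate(self, two_site_distance):
        point = SynchronyParams(0.6, 0.1, 200.0)
        mask = np.ones((2, 12), dtype=bool)
        fit = parametric_bootstrap(point, mask, two_site_distance, B=1, seed=3)
        assert fit.replicates.shape == (1, 3)
        np.testing.assert_array_equal(fit.median.as_array(), fit.replicates[0])

    def test_seeded_determinism(self, two_site_distance):
        point = SynchronyParams(0.6, 0.1, 200.0)
        mask = np.ones((2, 10), dtype=bool)
        a = parametric_bootstrap(point, mask, two_site_distance, B=4, seed=7)
        b = parametric_bootstrap(point, mask, two_site_distance, B=4, seed=7)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_simulated_mask_round_trip(self, two_site_distance):
        rng = np.random.default_rng(0)
        mask = rng.random((2, 15)) < 0.7
        mask[:, :2] = True
        sim = simulate_panel(SynchronyParams(0.8, 0.0, 300.0), mask, two_site_distance, rng)
        np.testing.assert_array_equal(sim.mask, mask)
        assert np.all(np.isfinite(sim.values[sim.mask]))
        assert np.all(np.isnan(sim.values[~sim.mask]))


class TestPairwiseCorrelations:
    def test_identical_series_correlate_perfectly(self, two_site_distance):
        values = np.tile(np.random.default_rng(1).normal(size=10), (2, 1))
        panel = make_panel(values, populations=["a", "b"])
        out = pairwise_empirical_correlations(panel, two_site_distance)
        assert len(out) == 1
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert out.loc[0, "n_overlap"] == 10
        assert out.loc[0, "distance_km"] == 300.0

    def test_anticorrelated_triplet(self, two_site_distance):
        panel = make_panel([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], populations=["a", "b"])
        out = pairwise_empirical_correlations(panel, two_site_distance, min_overlap=3)
        assert out.loc[0, "pearson_r"] == pytest.approx(-1.0)

    def test_overlap_threshold(self, two_site_distance):
        values = np.random.default_rng(2).normal(size=(2, 6))
        values[0, :2] = np.nan
        panel = make_panel(values, populations=["a", "b"])
        assert len(pairwise_empirical_correlations(panel, two_site_distance, min_overlap=5)) == 0
        assert len(pairwise_empirical_correlations(panel, two_site_distance, min_overlap=4)) == 1
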