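"""EM fitting: starts, E/M steps, convergence and parameter recovery."""

import numpy as np
import pytest
from scipy.stats import norm

from tetracall import (
    FitFailure,
    MeanModelParams,
    SimulationConfig,
    asr_transform,
    e_step,
    fit_mixture,
    hwe_proportions,
    m_step_means,
    m_step_proportions,
    mean_model_eval,
    parameter_count,
    simulate_marker,
    start_means_clustering,
    start_means_equidistant,
)
from tetracall.model import DOSAGES


def _simulated_y(model_id, params, p, sigma, n, seed, hwe=True, pi=None):
    cfg = SimulationConfig(
        model_id=model_id, params=params, p=p, sigma=sigma, n_samples=n,
        seed=seed, pi_mode="hwe" if hwe else "explicit", pi=pi,
    )
    rec, dosages, _ = simulate_marker(cfg)
    return asr_transform(rec["ratio"].to_numpy()), dosages


class TestStartMeans:
    def test_equidistant_grid(self):
        m = start_means_equidistant()
        assert m[0] == pytest.approx(0.142, abs=5e-4)
        assert m[-1] == pytest.approx(1.429, abs=5e-4)
        np.testing.assert_allclose(np.diff(m), (m[-1] - m[0]) / 4, atol=1e-12)
        assert np.all(np.diff(m) > 0)

    def test_clustering_recovers_tight_groups(self, rng):
        centers = np.array([0.1, 0.4, 0.8, 1.1, 1.4])
        y = (centers[:, None] + rng.normal(0, 0.01, (5, 20))).ravel()
        means = start_means_clustering(y)
        np.testing.assert_allclose(means, centers, atol=0.02)

    def test_identical_observations_degenerate(self):
        means = start_means_clustering(np.full(30, 0.7))
        assert np.ptp(means) == 0.0 and len(means) == 5

    def test_five_distinct_points_are_their_own_clusters(self):
        pts = np.array([0.1, 0.5, 0.8, 1.2, 1.5])
        np.testing.assert_allclose(start_means_clustering(pts), pts, atol=1e-12)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            start_means_clustering(np.array([0.1, 0.2]))


class TestEStep:
    def test_identical_means_give_prior(self):
        pi = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        post = e_step(np.array([0.3, 0.9]), np.full(5, 0.5), 0.1, pi)
        np.testing.assert_allclose(post, np.tile(pi, (2, 1)), atol=1e-12)

    def test_dominant_component(self):
        mu = np.arange(5) * 2.0  # 20 sigma apart
        post = e_step(np.array([4.0]), mu, 0.1, np.full(5, 0.2))
        np.testing.assert_allclose(post[0], [0, 0, 1, 0, 0], atol=1e-12)

    def test_matches_direct_density_ratios(self):
        mu = np.array([0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4, np.pi])
        sigma, pi = 0.1, np.full(5, 0.2)
        post = e_step(np.array([0.0]), mu, sigma, pi)
        dens = pi * norm.pdf(0.0, mu, sigma)
        np.testing.assert_allclose(post[0], dens / dens.sum(), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        y = rng.uniform(0, np.pi / 2, 100)
        post = e_step(y, np.linspace(0.1, 1.4, 5), 0.05, hwe_proportions(0.3))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestMStepProportions:
    def _hard(self, counts):
        return np.repeat(np.eye(5), counts, axis=0)

    def test_free_column_means(self):
        pi, p = m_step_proportions(self._hard([10, 20, 40, 20, 10]), False)
        np.testing.assert_allclose(pi, [0.1, 0.2, 0.4, 0.2, 0.1], atol=1e-12)
        assert p is None

    def test_hwe_degenerate_all_nulliplex(self):
        pi, p = m_step_proportions(self._hard([50, 0, 0, 0, 0]), True)
        assert p == pytest.approx(1.0)
        np.testing.assert_allclose(pi, [1, 0, 0, 0, 0], atol=1e-12)

    def test_hwe_binomial_counts(self):
        pi, p = m_step_proportions(self._hard([1, 4, 6, 4, 1]), True)
        assert p == pytest.approx(0.5, abs=1e-12)
        np.testing.assert_allclose(pi, hwe_proportions(0.5), atol=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            m_step_proportions(np.empty((0, 5)), True)


class TestMStepMeans:
    def test_noiseless_self_consistency(self):
        truth = MeanModelParams(1, 0.1, 0.1, 1.0)
        mu = mean_model_eval(truth, DOSAGES)
        y = np.repeat(mu, 20)
        post = np.repeat(np.eye(5), 20, axis=0)
        start = MeanModelParams(1, 0.3, 0.2, 1.5)
        params, sigma = m_step_means(y, post, 1, start)
        assert params.c1 == pytest.approx(0.1, abs=1e-6)
        assert params.c2 == pytest.approx(0.1, abs=1e-6)
        assert params.r == pytest.approx(1.0, abs=1e-6)
        assert sigma == pytest.approx(1e-4)  # floored

    def test_single_component_weights_underdetermined(self):
        y = np.full(50, 0.8)
        post = np.zeros((50, 5))
        post[:, 2] = 1.0
        current = MeanModelParams(1, 0.05, 0.05, 1.2)
        params, sigma = m_step_means(y, post, 1, current)
        # only one mean constrained: parameters stay bounded and admissible
        assert params.r > 0 and params.c1 >= 0 and params.c2 >= 0
        assert np.isfinite(mean_model_eval(params, DOSAGES)).all()

    def test_recovery_from_model2_data(self):
        truth = MeanModelParams(2, 0.08, 0.08, 1.4)
        y, dosages = _simulated_y(2, truth, 0.5, 0.03, 500, seed=3)
        post = np.zeros((500, 5))
        post[np.arange(500), dosages] = 1.0
        params, sigma = m_step_means(y, post, 2, MeanModelParams(2, 0.02, 0.02, 1.0))
        assert params.c == pytest.approx(0.08, rel=0.10)
        assert params.r == pytest.approx(1.4, rel=0.10)


class TestFitMixture:
    def test_clean_hwe_recovery(self):
        truth = MeanModelParams(1, 0.0, 0.0, 1.0)
        y, _ = _simulated_y(1, truth, 0.5, 0.04, 400, seed=7)
        fit = fit_mixture(y, 1, True, start_means_equidistant())
        assert fit.converged
        assert fit.p == pytest.approx(0.5, abs=0.05)
        np.testing.assert_allclose(fit.mu, mean_model_eval(truth, DOSAGES), atol=0.03)

    def test_single_cluster_collapse(self, rng):
        y = 0.05 + rng.normal(0, 0.01, 100).clip(-0.04, None)
        fit = fit_mixture(y, 2, False, start_means_equidistant())
        assert fit.pi[0] == pytest.approx(1.0, abs=0.05)

    def test_loglik_monotone(self):
        y, _ = _simulated_y(2, MeanModelParams(2, 0.05, 0.05, 0.8), 0.3, 0.05, 200, seed=5)
        for hwe in (True, False):
            fit = fit_mixture(y, 3, hwe, start_means_clustering(y))
            diffs = np.diff(fit.loglik_path)
            assert np.all(diffs >= -1e-8)

    def test_invariants_on_returned_fit(self):
        y, _ = _simulated_y(2, MeanModelParams(2, 0.05, 0.05, 0.8), 0.3, 0.05, 200, seed=5)
        fit = fit_mixture(y, 2, True, start_means_equidistant())
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert fit.pi.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(fit.pi, hwe_proportions(fit.p))
        np.testing.assert_array_equal(fit.mu, mean_model_eval(fit.params, DOSAGES))
        assert fit.bic == -2.0 * fit.loglik + parameter_count(2, True) * np.log(fit.n)

    def test_hwe_nested_in_free(self):
        y, _ = _simulated_y(1, MeanModelParams(1, 0.05, 0.1, 1.2), 0.4, 0.04, 300, seed=9)
        start = start_means_clustering(y)
        ll_free = fit_mixture(y, 1, False, start).loglik
        ll_hwe = fit_mixture(y, 1, True, start).loglik
        assert ll_free >= ll_hwe - 1e-6

    def test_degenerate_data_fails(self):
        with pytest.raises(FitFailure):
            fit_mixture(np.full(50, 0.7), 1, True, start_means_equidistant())

    def test_too_few_observations_fail(self):
        with pytest.raises(FitFailure):
            fit_mixture(np.linspace(0, 1, 5), 1, True, start_means_equidistant())
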