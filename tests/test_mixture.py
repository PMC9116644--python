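"""Hard-EM mixture driver: initialization, E/M steps, full fits."""

import numpy as np
import pytest

from diriclust.dirichlet import DirichletParams, GammaPrior, fit_bayes, log_density, sample
from diriclust.mixture import (
    FitConfig,
    MixtureParams,
    Responsibilities,
    fit,
    hard_assign,
    initialize,
    log_likelihood,
    m_step,
    responsibilities,
)
from diriclust.simulate import scheme1


@pytest.fixture(scope="module")
def two_blob_data():
    rng = np.random.default_rng(0)
    a = rng.dirichlet([40, 5, 5], size=150)
    b = rng.dirichlet([5, 5, 40], size=100)
    return np.vstack([a, b]), np.r_[np.zeros(150, int), np.ones(100, int)]


class TestInitialize:
    def test_alpha_rows_sum_to_c_and_match_blobs(self, two_blob_data):
        x, _ = two_blob_data
        params = initialize(x, 2, FitConfig(seed=0, init_scale_c=60))
        np.testing.assert_allclose(params.alphas.sum(axis=1), 60.0, rtol=1e-6)
        means = params.alphas / params.alphas.sum(axis=1, keepdims=True)
        blob_means = sorted(m[0] for m in means)
        assert blob_means[0] < 0.3 and blob_means[1] > 0.6

    def test_deterministic_given_seed(self, two_blob_data):
        x, _ = two_blob_data
        p1 = initialize(x, 3, FitConfig(seed=5))
        p2 = initialize(x, 3, FitConfig(seed=5))
        np.testing.assert_array_equal(p1.alphas, p2.alphas)
        np.testing.assert_array_equal(p1.pi, p2.pi)

    def test_k1_uses_column_means(self, two_blob_data):
        x, _ = two_blob_data
        params = initialize(x, 1, FitConfig(init_scale_c=60))
        np.testing.assert_allclose(params.alphas[0], 60 * x.mean(axis=0))
        np.testing.assert_array_equal(params.pi, [1.0])


class TestResponsibilities:
    def test_k1_all_ones(self, two_blob_data):
        x, _ = two_blob_data
        params = MixtureParams(np.array([[2.0, 2.0, 2.0]]), np.array([1.0]))
        g = responsibilities(x, params).gamma
        np.testing.assert_allclose(g, 1.0)

    def test_identical_components_split_evenly(self, two_blob_data):
        x, _ = two_blob_data
        params = MixtureParams(np.array([[3.0, 2.0, 1.0]] * 2), np.array([0.5, 0.5]))
        g = responsibilities(x, params).gamma
        np.testing.assert_allclose(g, 0.5, atol=1e-12)

    def test_matches_direct_two_density_evaluation(self):
        x = np.array([[0.5, 0.5]])
        a1, a2 = DirichletParams([2.0, 2.0]), DirichletParams([20.0, 2.0])
        params = MixtureParams(np.array([a1.alpha, a2.alpha]), np.array([0.5, 0.5]))
        g = responsibilities(x, params).gamma[0]
        w = np.exp([log_density(x[0], a1), log_density(x[0], a2)])
        np.testing.assert_allclose(g, w / w.sum(), rtol=1e-12)

    def test_no_underflow_at_large_concentrations(self):
        rng = np.random.default_rng(1)
        x = rng.dirichlet([50, 50, 50], size=20)
        params = MixtureParams(
            np.array([[5000.0, 2000.0, 3000.0], [2.0, 2.0, 2.0]]), np.array([0.5, 0.5])
        )
        g = responsibilities(x, params).gamma
        assert np.all(np.isfinite(g))
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-10)


class TestLogLikelihood:
    def test_k1_flat_density_is_n_log_two(self):
        rng = np.random.default_rng(2)
        x = rng.dirichlet([2, 2, 2], size=37)
        params = MixtureParams(np.array([[1.0, 1.0, 1.0]]), np.array([1.0]))
        assert log_likelihood(x, params) == pytest.approx(37 * np.log(2.0))

    def test_duplicating_rows_doubles_value(self, two_blob_data):
        x, _ = two_blob_data
        params = MixtureParams(
            np.array([[4.0, 1.0, 1.0], [1.0, 1.0, 4.0]]), np.array([0.6, 0.4])
        )
        assert log_likelihood(np.vstack([x, x]), params) == pytest.approx(
            2 * log_likelihood(x, params)
        )

    def test_single_point_hand_computation(self):
        x = np.array([[0.3, 0.7]])
        a1, a2 = DirichletParams([2.0, 5.0]), DirichletParams([6.0, 2.0])
        pi = np.array([0.3, 0.7])
        params = MixtureParams(np.array([a1.alpha, a2.alpha]), pi)
        expect = np.log(
            0.3 * np.exp(log_density(x[0], a1)) + 0.7 * np.exp(log_density(x[0], a2))
        )
        assert log_likelihood(x, params) == pytest.approx(expect, rel=1e-12)

    def test_invariant_under_component_relabeling(self, two_blob_data):
        x, _ = two_blob_data
        alphas = np.array([[4.0, 1.0, 1.0], [1.0, 1.0, 4.0]])
        pi = np.array([0.6, 0.4])
        ll = log_likelihood(x, MixtureParams(alphas, pi))
        ll_perm = log_likelihood(x, MixtureParams(alphas[::-1], pi[::-1]))
        assert ll == pytest.approx(ll_perm, rel=1e-12)


class TestHardAssign:
    def test_argmax_and_tie_break(self):
        g = np.array([[0.1, 0.7, 0.2], [0.5, 0.5, 0.0], [0.2, 0.2, 0.6]])
        np.testing.assert_array_equal(hard_assign(g), [1, 0, 2])

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        g = rng.dirichlet([1, 1, 1], size=50)
        perm = np.array([2, 0, 1])
        lab = hard_assign(g)
        lab_perm = hard_assign(g[:, perm])
        np.testing.assert_array_equal(perm[lab_perm], lab)


class TestMStep:
    def test_empty_cluster_gets_initial_alpha_back(self, two_blob_data):
        x, _ = two_blob_data
        cfg = FitConfig(seed=0)
        params = initialize(x, 2, cfg)
        a0 = params.alphas.copy()
        labels = np.zeros(x.shape[0], dtype=int)  # cluster 1 empty
        gamma = Responsibilities(np.column_stack([np.ones(x.shape[0]), np.zeros(x.shape[0])]))
        new, empty, _ = m_step(x, labels, gamma, params, a0, cfg)
        assert empty == 1
        np.testing.assert_array_equal(new.alphas[1], a0[1])

    def test_pi_from_soft_counts(self, two_blob_data):
        x, _ = two_blob_data
        n = x.shape[0]
        cfg = FitConfig(seed=0)
        params = initialize(x, 2, cfg)
        g = np.column_stack([np.full(n, 2 / 3), np.full(n, 1 / 3)])
        labels = np.zeros(n, dtype=int)
        new, _, _ = m_step(x, labels, Responsibilities(g), params, params.alphas, cfg)
        np.testing.assert_allclose(new.pi, [2 / 3, 1 / 3])

    def test_clean_labels_recover_generating_parameters(self, two_blob_data):
        x, labels = two_blob_data
        cfg = FitConfig(seed=0)
        params = initialize(x, 2, cfg)
        g = np.eye(2)[labels]
        new, _, _ = m_step(x, labels, Responsibilities(g), params, params.alphas, cfg)
        # align estimated clusters with generating components by first coordinate
        order = np.argsort(-new.alphas[:, 0])
        np.testing.assert_allclose(new.alphas[order[0]], [40, 5, 5], rtol=0.3)
        np.testing.assert_allclose(new.alphas[order[1]], [5, 5, 40], rtol=0.3)

    def test_small_cluster_bayes_branch_and_printed_switch(self):
        rng = np.random.default_rng(8)
        big = rng.dirichlet([10, 5, 5], size=200)
        small = rng.dirichlet([5, 5, 30], size=10)
        x = np.vstack([big, small])
        labels = np.r_[np.zeros(200, int), np.ones(10, int)]
        g = np.eye(2)[labels]
        params = MixtureParams(np.array([[10.0, 5.0, 5.0], [5.0, 5.0, 30.0]]),
                               np.array([200 / 210, 10 / 210]))
        cfg2 = FitConfig(variant="hard_dmm_2", seed=0)
        new, _, _ = m_step(x, labels, Responsibilities(g), params, params.alphas, cfg2)
        bayes_small = fit_bayes(small, GammaPrior(1, 1)).alpha
        np.testing.assert_allclose(new.alphas[1], bayes_small, rtol=1e-12)

        cfg_printed = FitConfig(variant="hard_dmm_2", threshold_direction="as_printed", seed=0)
        new_p, _, _ = m_step(x, labels, Responsibilities(g), params, params.alphas, cfg_printed)
        bayes_big = fit_bayes(big, GammaPrior(1, 1)).alpha
        np.testing.assert_allclose(new_p.alphas[0], bayes_big, rtol=1e-12)
        assert not np.allclose(new_p.alphas[1], bayes_small)


class TestFit:
    def test_k1_is_single_mle(self, two_blob_data):
        x, _ = two_blob_data
        res = fit(x, 1, FitConfig(seed=0))
        assert res.converged and res.n_iter == 1
        assert len(res.loglik_trace) == 2
        np.testing.assert_array_equal(res.labels, 0)

    def test_terminates_on_degenerate_duplicate_components(self):
        rng = np.random.default_rng(3)
        x = rng.dirichlet([10, 10, 10], size=120)
        res = fit(x, 2, FitConfig(seed=0, max_iter=200))
        assert res.n_iter <= 200
        assert set(np.unique(res.labels)) <= {0, 1}

    def test_two_blobs_clustered_correctly(self, two_blob_data):
        x, truth = two_blob_data
        res = fit(x, 2, FitConfig(seed=0))
        agreement = max(
            np.mean(res.labels == truth), np.mean(res.labels == 1 - truth)
        )
        assert agreement > 0.97

    def test_trace_invariants_and_final_not_below_initial(self, two_blob_data):
        x, _ = two_blob_data
        res = fit(x, 2, FitConfig(seed=0))
        assert len(res.loglik_trace) == res.n_iter + 1
        assert res.loglik_trace[-1] >= res.loglik_trace[0]
        assert np.all(res.params.alphas > 0)
        assert res.params.pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_variants_identical_without_small_clusters(self):
        """Both hard-EM variants coincide when no cluster is ever small."""
        data = scheme1(3)
        r1 = fit(data.data, 3, FitConfig(variant="hard_dmm_1", seed=3))
        r2 = fit(data.data, 3, FitConfig(variant="hard_dmm_2", seed=3))
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_allclose(r1.params.alphas, r2.params.alphas)

    def test_result_serializes_to_json(self, two_blob_data):
        import json

        x, _ = two_blob_data
        res = fit(x, 2, FitConfig(seed=0))
        doc = json.loads(res.to_json())
        assert len(doc["labels"]) == x.shape[0]
        assert len(doc["alphas"]) == 2
        assert doc["converged"] is True
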