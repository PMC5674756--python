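import math

import numpy as np
import pytest
from scipy.special import digamma, gammaln

from pathfa.data_io import ExpressionMatrix
from pathfa.gene_sets import AnnotationMatrix
from pathfa.inference import (
    FitConfig,
    PseudoData,
    _jj_lambda,
    compute_elbo,
    compute_pseudo_data,
    fit,
    update_ard,
    update_factor_states,
    update_weights,
)
from pathfa.model_core import (
    FactorSpec,
    Hyperparameters,
    ModelState,
    assemble_model,
    initialize_state,
)
from pathfa.simulate import SimulationConfig, simulate_dataset

from ._oracles import enumerate_spike_slab, single_gene_factor_state
from .conftest import make_annotation, make_expression


def _pseudo_for(state, y, tau):
    y = np.atleast_2d(np.asarray(y, float)).T if np.ndim(y) == 1 else y
    return PseudoData(T=y, B=np.full_like(y, tau))


class TestCoupledSpikeSlabOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("pi", [0.5, 0.1])
    def test_single_gene_single_factor_matches_enumeration(self, seed, pi):
        rng = np.random.default_rng(seed)
        n = 6
        x = rng.standard_normal(n)
        tau, alpha = 4.0, 1.5
        w_true = rng.standard_normal() / np.sqrt(alpha)
        y = x * w_true + rng.standard_normal(n) / np.sqrt(tau)

        state = single_gene_factor_state(y, x, tau, alpha, pi)
        ps = _pseudo_for(state, y, tau)
        for _ in range(2):  # fixed point after one update
            update_weights(state, ps)
        g_ref, m_ref, v_ref = enumerate_spike_slab(y, x, tau, alpha, pi)
        assert state.gamma[0, 0] == pytest.approx(g_ref, abs=1e-8)
        assert state.W_mean1[0, 0] == pytest.approx(m_ref, abs=1e-8)
        assert state.W_var1[0, 0] == pytest.approx(v_ref, abs=1e-8)

    def test_uninformative_data_gives_annotation_implied_posterior(self):
        # zero observations: the indicator log-odds reduce to the prior,
        # the annotation evidence, and the Occam factor of the slab
        rng = np.random.default_rng(3)
        n, tau, alpha = 8, 2.0, 1.0
        x = rng.standard_normal(n)
        hyper = Hyperparameters()
        ann = AnnotationMatrix(
            np.array([[1], [0]], dtype=np.int8),
            np.array(["g0", "g1"], dtype=object),
            np.array(["s0"], dtype=object),
        )
        big = 1e12
        state = ModelState(
            spec=[FactorSpec("s0", "annotated", prior_pi=0.5, annotation_column=0)],
            annotation=ann, hyper=hyper, noise="gaussian", n_cells=n,
            cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
            gene_ids=ann.gene_ids,
            X_mean=x[:, None], X_var=np.zeros((n, 1)),
            gamma=np.full((2, 1), 0.5),
            W_mean1=np.zeros((2, 1)), W_var1=np.ones((2, 1)),
            alpha_shape=np.array([big]), alpha_rate=np.array([big / alpha]),
            tau_shape=np.array([big, big]), tau_rate=np.array([big / tau] * 2),
            gene_means=np.zeros(2), initialized=True,
        )
        ps = PseudoData(T=np.zeros((n, 2)), B=np.full((n, 2), tau))
        update_weights(state, ps)
        rho = alpha + tau * np.sum(x**2)
        occam = 0.5 * (math.log(alpha) - math.log(rho))
        for g, I in enumerate([1, 0]):
            evid = (
                math.log(0.99) - math.log(hyper.fnr)
                if I
                else math.log(hyper.fpr) - math.log1p(-hyper.fnr)
            )
            expected = 1.0 / (1.0 + math.exp(-(evid + occam)))
            assert state.gamma[g, 0] == pytest.approx(expected, rel=1e-6)


class TestFactorStateUpdate:
    def test_matches_conjugate_bayesian_regression(self):
        rng = np.random.default_rng(0)
        n, tau, w = 12, 3.0, 0.7
        y = rng.standard_normal(n)
        state = single_gene_factor_state(y, np.zeros(n), tau, 1.0, 0.5)
        state.X_var[:] = 1.0
        state.gamma[:] = 1.0
        state.W_mean1[:] = w
        state.W_var1[:] = 0.0
        ps = _pseudo_for(state, y, tau)
        update_factor_states(state, ps)
        prec = 1.0 + tau * w**2
        assert np.allclose(state.X_mean[:, 0], tau * w * y / prec, atol=1e-10)
        assert np.allclose(state.X_var[:, 0], 1.0 / prec, atol=1e-10)

    def test_zero_weights_revert_to_prior(self):
        rng = np.random.default_rng(1)
        n = 9
        y = rng.standard_normal(n)
        state = single_gene_factor_state(y, rng.standard_normal(n), 2.0, 1.0, 0.5)
        state.gamma[:] = 0.0
        state.W_mean1[:] = 0.0
        ps = _pseudo_for(state, y, 2.0)
        update_factor_states(state, ps)
        assert np.allclose(state.X_mean[:, 0], 0.0)
        assert np.allclose(state.X_var[:, 0], 1.0)


class TestArdUpdate:
    def _toy_state(self, G, gamma, mu, var):
        state = single_gene_factor_state([0.0], [0.0], 1.0, 1.0, 0.5)
        state.gamma = np.full((G, 1), gamma)
        state.W_mean1 = np.full((G, 1), mu)
        state.W_var1 = np.full((G, 1), var)
        state.alpha_shape = np.array([1.0])
        state.alpha_rate = np.array([1.0])
        state.gene_ids = np.array([f"g{i}" for i in range(G)], dtype=object)
        state.annotation = AnnotationMatrix(
            np.zeros((G, 0), dtype=np.int8), state.gene_ids,
            np.array([], dtype=object),
        )
        return state

    def test_all_spikes_recover_prior(self):
        state = self._toy_state(50, gamma=0.0, mu=1.0, var=1.0)
        update_ard(state)
        assert state.alpha_shape[0] == pytest.approx(state.hyper.ard_a)
        assert state.alpha_rate[0] == pytest.approx(state.hyper.ard_b)

    def test_full_slab_closed_form(self):
        G, v = 40, 0.25
        state = self._toy_state(G, gamma=1.0, mu=0.0, var=v)
        update_ard(state)
        assert state.alpha_shape[0] == pytest.approx(state.hyper.ard_a + G / 2)
        assert state.alpha_rate[0] == pytest.approx(state.hyper.ard_b + G * v / 2)

    def test_unit_weight_variance_recovered(self):
        rng = np.random.default_rng(0)
        G = 500
        w = rng.standard_normal(G)
        state = self._toy_state(G, gamma=1.0, mu=0.0, var=0.0)
        state.W_mean1[:, 0] = w
        update_ard(state)
        relevance = state.alpha_rate[0] / (state.alpha_shape[0] - 1)
        assert abs(relevance - 1.0) < 0.2


class TestNoiseUpdate:
    def _fit_noise_only(self, values):
        Y = make_expression(values)
        ann = make_annotation(values.shape[1], {})
        state = assemble_model(Y, ann, n_sparse=0, n_dense=0)
        state = initialize_state(state, Y, seed=0)
        return fit(state, Y, FitConfig(max_iter=10, tol=1e-8, min_iter=3)), Y

    def test_pure_noise_sd_recovered(self):
        rng = np.random.default_rng(0)
        fitted, _ = self._fit_noise_only(0.1 * rng.standard_normal((500, 4)))
        st = fitted.state
        e_sigma = np.sqrt(st.tau_rate / (st.tau_shape - 1))
        assert np.all(np.abs(e_sigma - 0.1) / 0.1 < 0.1)

    def test_heteroscedastic_ratio(self):
        rng = np.random.default_rng(1)
        vals = np.column_stack(
            [0.1 * rng.standard_normal(500), 1.0 * rng.standard_normal(500)]
        )
        fitted, _ = self._fit_noise_only(vals)
        st = fitted.state
        sigma2 = st.tau_rate / (st.tau_shape - 1)
        ratio = sigma2[1] / sigma2[0]
        assert 100 / 1.5 < ratio < 100 * 1.5

    def test_zero_residuals_guarded_by_prior_rate(self):
        fitted, _ = self._fit_noise_only(np.zeros((20, 3)) + np.eye(20, 3) * 0)
        st = fitted.state
        assert np.all(st.tau_rate >= st.hyper.noise_b)
        assert np.all(np.isfinite(st.e_tau()))


class TestPseudoData:
    def test_hurdle_without_zeros_equals_gaussian_path(self):
        rng = np.random.default_rng(0)
        raw = np.abs(rng.standard_normal((15, 20))) + 0.5
        ann = make_annotation(20, {"s": range(8)})
        Yh = make_expression(raw)
        Yg = make_expression(np.log1p(raw))
        sh = initialize_state(
            assemble_model(Yh, ann, n_sparse=0, n_dense=0, noise="hurdle"), Yh, 0
        )
        sg = initialize_state(
            assemble_model(Yg, ann, n_sparse=0, n_dense=0), Yg, 0
        )
        ph = compute_pseudo_data(sh, Yh)
        pg = compute_pseudo_data(sg, Yg)
        assert np.allclose(ph.T, pg.T, atol=1e-12)
        assert np.allclose(ph.B, pg.B, atol=1e-12)

    def test_jaakkola_bound_tangent_at_origin(self):
        assert _jj_lambda(np.array([0.0]))[0] == pytest.approx(0.125)
        # bound value at xi=0, E[f]=0 equals the exact logistic term -log 2
        xi, F, F2 = 0.0, 0.0, 0.0
        lam = 0.125
        val = -np.logaddexp(0, xi) + (xi - F) / 2 - lam * (F2 - xi**2)
        assert val == pytest.approx(-math.log(2))

    def test_poisson_link_at_zero(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(10, 6)).astype(float)
        counts[0, 0] = 0.0
        Y = make_expression(counts, scale="raw_counts")
        ann = make_annotation(6, {})
        state = assemble_model(Y, ann, n_sparse=0, n_dense=1, noise="poisson")
        state = initialize_state(state, Y, seed=0)
        state.X_mean[:] = 0.0
        state.W_mean1[:] = 0.0
        ps = compute_pseudo_data(state, Y)
        # lambda(0) = log 2 and log P(y=0 | f=0) = -log 2
        assert ps.gval[0, 0] == pytest.approx(-math.log(2))

    def test_negative_counts_rejected(self):
        Y = make_expression(-np.ones((3, 3)))
        ann = make_annotation(3, {})
        state = assemble_model(Y, ann, n_sparse=0, n_dense=0)
        state = initialize_state(state, Y, seed=0)
        state.noise = "hurdle"
        with pytest.raises(ValueError, match="negative"):
            compute_pseudo_data(state, Y)


class TestElbo:
    def test_zero_factor_model_equals_exact_marginal(self):
        # with only tau unknown the factorized posterior is exact, so the
        # bound attains the closed-form marginal likelihood
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((30, 5))
        Y = make_expression(vals)
        ann = make_annotation(5, {})
        state = assemble_model(Y, ann, n_sparse=0, n_dense=0)
        state = initialize_state(state, Y, seed=0)
        ps = compute_pseudo_data(state, Y)
        from pathfa.inference import update_noise

        update_noise(state, ps)
        elbo = compute_elbo(state, Y, ps)

        a, b = state.hyper.noise_a, state.hyper.noise_b
        N = Y.n_cells
        yc = vals - vals.mean(0)
        marginal = 0.0
        for g in range(Y.n_genes):
            ss = np.sum(yc[:, g] ** 2)
            marginal += (
                gammaln(a + N / 2) - gammaln(a) + a * math.log(b)
                - (a + N / 2) * math.log(b + ss / 2) - N / 2 * math.log(2 * math.pi)
            )
        assert elbo == pytest.approx(marginal, abs=1e-6)

    def test_ascent_on_random_problems(self):
        rng = np.random.default_rng(0)
        for trial in range(6):
            N, G = int(rng.integers(15, 40)), int(rng.integers(30, 80))
            ann = make_annotation(G, {"s0": range(10), "s1": range(15, 25)})
            vals = rng.standard_normal((N, G))
            noise = "gaussian"
            if trial % 2:
                vals = np.abs(vals)
                vals[rng.random((N, G)) < 0.3] = 0.0
                noise = "hurdle"
            Y = make_expression(vals)
            state = assemble_model(Y, ann, n_sparse=1, n_dense=1, noise=noise)
            state = initialize_state(state, Y, seed=trial)
            fitted = fit(state, Y, FitConfig(max_iter=25, tol=1e-12, min_iter=25))
            tr = np.array(fitted.state.elbo_trace)
            rel = np.diff(tr) / (np.abs(tr[:-1]) + 1e-12)
            assert rel.min() > -1e-8


@pytest.fixture(scope="module")
def recovery_fit():
    cfg = SimulationConfig(
        n_cells=100, n_genes=500, n_active_pathways=3,
        n_negative_pathways=5, set_size_range=(30, 50), noise_sd=0.1,
        seed=17,
    )
    sim = simulate_dataset(cfg)
    state = assemble_model(sim.Y, sim.true_annotation, n_sparse=0, n_dense=1)
    state = initialize_state(state, sim.Y, seed=17)
    return fit(state, sim.Y, FitConfig(max_iter=400, tol=1e-5)), sim


class TestFit:
    def test_converges_and_recovers_true_factors(self, recovery_fit):
        fitted, sim = recovery_fit
        assert fitted.converged
        from pathfa.downstream import factor_relevance

        report = factor_relevance(fitted)
        top3 = {f.name for f in report.factors[:3]}
        assert top3 == {"active_1", "active_2", "active_3"}

    def test_posterior_states_correlate_with_truth(self, recovery_fit):
        fitted, sim = recovery_fit
        st = fitted.state
        for j in range(3):
            k = st.factor_index(f"active_{j + 1}")
            cors = [
                abs(np.corrcoef(st.X_mean[:, k], sim.X_true[:, i])[0, 1])
                for i in range(3)
            ]
            assert max(cors) > 0.95

    def test_inactive_sets_deactivated(self, recovery_fit):
        fitted, _ = recovery_fit
        from pathfa.downstream import factor_relevance

        rel = factor_relevance(fitted).as_dict()
        active = [rel[f"active_{j + 1}"] for j in range(3)]
        for name, v in rel.items():
            if name.startswith("negative"):
                assert v < 0.05 * np.median(active)

    def test_huge_tol_stops_at_min_iter(self, small_sim):
        state = assemble_model(small_sim.Y, small_sim.corrupted_annotation,
                               n_sparse=0, n_dense=1)
        state = initialize_state(state, small_sim.Y, seed=0)
        fitted = fit(state, small_sim.Y, FitConfig(max_iter=50, tol=1e6, min_iter=7))
        assert fitted.converged and fitted.n_iter == 7

    def test_fit_deterministic_given_seed(self, small_sim):
        runs = []
        for _ in range(2):
            st = assemble_model(small_sim.Y, small_sim.corrupted_annotation,
                                n_sparse=1, n_dense=1)
            st = initialize_state(st, small_sim.Y, seed=5)
            runs.append(fit(st, small_sim.Y, FitConfig(max_iter=30, tol=1e-12)))
        assert np.array_equal(runs[0].state.X_mean, runs[1].state.X_mean)
        assert runs[0].state.elbo_trace == runs[1].state.elbo_trace

    def test_unfitted_state_rejected(self, small_sim):
        state = assemble_model(small_sim.Y, small_sim.corrupted_annotation)
        with pytest.raises(ValueError, match="initialize"):
            fit(state, small_sim.Y)

    def test_dense_factor_saturates_on_global_signal(self):
        rng = np.random.default_rng(2)
        N, G = 40, 60
        x = rng.standard_normal(N)
        w = rng.standard_normal(G) + 2.0
        Y = make_expression(np.outer(x, w) + 0.05 * rng.standard_normal((N, G)))
        ann = make_annotation(G, {})
        state = assemble_model(Y, ann, n_sparse=0, n_dense=1)
        state = initialize_state(state, Y, seed=0)
        fitted = fit(state, Y, FitConfig(max_iter=40, tol=1e-8))
        k = fitted.state.factor_index("dense_1")
        assert np.all(fitted.state.gamma[:, k] > 0.99)
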