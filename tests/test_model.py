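"""Likelihood primitives, MCMC behaviour, posterior summaries and FDR rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ribote.counts import drop_all_zero_genes, reference_normalize
from ribote.model import (
    LatentState,
    ModelSpec,
    bayesian_fdr_select,
    convergence_diagnostics,
    fit_mcmc,
    joint_loglik,
    posterior_change_prob,
    summarize,
    zip_logpmf,
)
from ribote.simulate import SimConfig, simulate_counts
from tests.conftest import make_count_matrix


def fitted_matrix(config):
    cm, truth = simulate_counts(config)
    cm = reference_normalize(drop_all_zero_genes(cm), config.ref_gene_id)
    return cm, truth


class TestZipLogpmf:
    def test_reduces_to_poisson_at_pi_zero(self):
        y = np.arange(0, 30)
        for lam in (0.5, 3.0, 20.0):
            assert np.allclose(
                zip_logpmf(y, lam, 0.0),
                stats.poisson.logpmf(y, lam),
                atol=1e-12,
            )

    def test_zero_rate_limit(self):
        assert zip_logpmf(0, 0.0, 0.0) == pytest.approx(0.0)
        assert zip_logpmf(1, 0.0, 0.0) == -np.inf

    def test_direct_numeric_value(self):
        expected = np.log(0.3 + 0.7 * np.exp(-2.0))
        assert zip_logpmf(0, 2.0, 0.3) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pi", [0.0, 0.1, 0.5, 0.9])
    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 20.0, 50.0])
    def test_normalizes_over_support(self, pi, lam):
        y = np.arange(0, 200)
        total = np.exp(zip_logpmf(y, lam, pi)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            zip_logpmf(-1, 1.0, 0.5)
        with pytest.raises(ValueError):
            zip_logpmf(0, 1.0, 1.5)


class TestJointLoglik:
    def one_gene_cm(self, y, sf):
        cm = make_count_matrix(np.array([y]), times=(0, 12), size_factors=sf)
        return cm

    def test_matches_hand_computed_pmf_sum(self):
        # libraries: rpf_t0, rpf_t12, rna_t0, rna_t12
        y = [4, 0, 7, 12]
        sf = np.array([1.0, 2.0, 0.5, 1.0])
        mu, rho, delta, pi = 6.0, 1.8, 0.5, 0.2
        state = LatentState(
            log_mu=np.array([np.log(mu)]),
            log_rho=np.array([[np.log(rho)]]),
            z=np.array([1]),
            delta=np.array([delta]),
            eta=np.zeros(2),
            pi=pi,
            p0=0.8,
            sigma_pair=0.0,
        )
        cm = self.one_gene_cm(y, sf)
        lam = [sf[0] * mu, sf[1] * mu * rho * delta, sf[2] * mu, sf[3] * mu * rho]
        expected = (
            np.log(0.0 + (1 - pi) * stats.poisson.pmf(4, lam[0]))
            + np.log(pi + (1 - pi) * stats.poisson.pmf(0, lam[1]))
            + stats.poisson.logpmf(7, lam[2])
            + stats.poisson.logpmf(12, lam[3])
        )
        assert joint_loglik(state, cm) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance_of_rate_product(self):
        y = [3, 5, 2, 8]
        state = LatentState(
            log_mu=np.array([1.0]), log_rho=np.array([[0.3]]),
            z=np.array([0]), delta=np.array([1.0]), eta=np.zeros(2),
            pi=0.1, p0=0.9, sigma_pair=0.0,
        )
        cm1 = self.one_gene_cm(y, np.full(4, 2.0))
        state2 = LatentState(
            log_mu=state.log_mu + np.log(2), log_rho=state.log_rho,
            z=state.z, delta=state.delta, eta=state.eta,
            pi=0.1, p0=0.9, sigma_pair=0.0,
        )
        cm2 = self.one_gene_cm(y, np.full(4, 1.0))
        assert joint_loglik(state, cm1) == pytest.approx(joint_loglik(state2, cm2))

    def test_degenerate_full_zero_inflation(self):
        y = [0, 0, 1, 1]
        state = LatentState(
            log_mu=np.array([0.0]), log_rho=np.array([[0.0]]),
            z=np.array([0]), delta=np.array([1.0]), eta=np.zeros(2),
            pi=1.0, p0=0.9, sigma_pair=0.0,
        )
        cm = self.one_gene_cm(y, np.ones(4))
        # RPF zero observations contribute log(1) = 0 each
        expected = stats.poisson.logpmf(1, 1.0) * 2
        assert joint_loglik(state, cm) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        state = LatentState(
            log_mu=np.zeros(3), log_rho=np.zeros((3, 1)), z=np.zeros(3, int),
            delta=np.ones(3), eta=np.zeros(2), pi=0.1, p0=0.9, sigma_pair=0.0,
        )
        cm = self.one_gene_cm([1, 1, 1, 1], np.ones(4))
        with pytest.raises(ValueError):
            joint_loglik(state, cm)


class TestPosteriorChangeProb:
    def make_draws(self, delta, z, theta=2.0):
        from ribote.model import PosteriorDraws

        delta = np.asarray(delta, float)[None, :, None]
        z = np.asarray(z, np.int8)[None, :, None]
        K = delta.shape[1]
        return PosteriorDraws(
            gene_ids=["g"], delta=delta, z=z,
            log_mu=np.zeros((1, K, 1)), log_rho=np.zeros((1, K, 1, 1)),
            eta=np.zeros((1, K, 1)), pi=np.zeros((1, K)), p0=np.zeros((1, K)),
            sigma_pair=np.zeros((1, K)), acceptance={}, later_times=[12],
            contrast_time=12, spec=ModelSpec(theta=theta),
        )

    def test_all_spike_gives_zero(self):
        d = self.make_draws([1.0] * 10, [0] * 10)
        assert posterior_change_prob(d, 2.0).iloc[0] == 0.0

    def test_direct_counting(self):
        d = self.make_draws([3.0, 1.2] * 5, [1] * 10)
        assert posterior_change_prob(d, 2.0).iloc[0] == pytest.approx(0.5)

    def test_theta_near_one_recovers_slab_probability(self):
        d = self.make_draws([1.5, 1.0, 0.9, 2.0], [1, 0, 1, 1])
        assert posterior_change_prob(d, 1.0 + 1e-9).iloc[0] == pytest.approx(0.75)

    def test_monotone_nonincreasing_in_theta(self):
        rng = np.random.default_rng(0)
        delta = rng.gamma(2, 0.5, size=200)
        z = (rng.random(200) < 0.6).astype(int)
        delta = np.where(z == 0, 1.0, delta)
        d = self.make_draws(delta, z)
        qs = [posterior_change_prob(d, t).iloc[0] for t in (1.2, 1.5, 2.0, 3.0, 5.0)]
        assert all(a >= b for a, b in zip(qs, qs[1:]))

    def test_invalid_theta(self):
        d = self.make_draws([1.0], [0])
        with pytest.raises(ValueError):
            posterior_change_prob(d, 1.0)


def brute_force_prefix_select(q, alpha):
    """Independent oracle: explicit loop over every q-descending prefix."""
    order = sorted(range(len(q)), key=lambda i: -q[i])
    best_k, best_err = 0, 0.0
    for k in range(1, len(q) + 1):
        err = sum(1.0 - q[i] for i in order[:k]) / k
        if err <= alpha:
            best_k, best_err = k, err
    sel = np.zeros(len(q), bool)
    sel[order[:best_k]] = True
    return sel, best_err


class TestFdrSelect:
    def test_certain_genes_all_selected(self):
        sel, fdr = bayesian_fdr_select([1.0, 1.0, 1.0], 0.05)
        assert sel.all() and fdr == 0.0

    def test_prefix_enumeration_example(self):
        sel, _ = bayesian_fdr_select([0.99, 0.97, 0.6, 0.2], 0.05)
        assert sel.sum() == 2 and sel[0] and sel[1]

    def test_alpha_one_selects_everything(self):
        sel, _ = bayesian_fdr_select([0.1, 0.0, 0.7], 1.0)
        assert sel.all()

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(1, 40)
            q = rng.random(n).round(3)
            alpha = float(rng.uniform(0.01, 0.5))
            sel, fdr = bayesian_fdr_select(q, alpha)
            sel_bf, fdr_bf = brute_force_prefix_select(list(q), alpha)
            assert sel.sum() == sel_bf.sum()
            assert fdr == pytest.approx(fdr_bf)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        q=st.lists(st.floats(0, 1), min_size=1, max_size=30),
        alpha=st.floats(0.01, 0.99),
    )
    def test_selected_set_satisfies_bound(self, q, alpha):
        sel, fdr = bayesian_fdr_select(q, alpha)
        if sel.any():
            assert np.mean(1.0 - np.asarray(q)[sel]) <= alpha + 1e-12
            assert fdr <= alpha + 1e-12


class TestMcmc:
    @pytest.fixture(scope="class")
    def small_fit(self):
        cfg = SimConfig(
            n_genes=250, times=(0, 12), lib_depth=250_000.0, p0=0.8,
            sigma_pair=0.05, lib_size_sd=0.1, seed=13,
        )
        cm, truth = fitted_matrix(cfg)
        spec = ModelSpec(n_chains=2, n_iter=1200, n_burnin=300, thin=2, seed=99)
        return fit_mcmc(cm, spec), truth, cm, spec

    def test_spike_slab_consistency_every_draw(self, small_fit):
        draws, *_ = small_fit
        z, delta = draws.flat("z"), draws.flat("delta")
        assert np.all(delta[z == 0] == 1.0)

    def test_draw_counts_match_controls(self, small_fit):
        draws, _, _, spec = small_fit
        kept = (spec.n_iter - spec.n_burnin) // spec.thin
        assert draws.delta.shape[:2] == (spec.n_chains, kept)

    def test_reproducible_given_seed(self):
        cfg = SimConfig(n_genes=40, times=(0, 12), lib_depth=40_000.0, seed=3)
        cm, _ = fitted_matrix(cfg)
        spec = ModelSpec(n_chains=1, n_iter=200, n_burnin=50, thin=1, seed=5)
        a = fit_mcmc(cm, spec)
        b = fit_mcmc(cm, spec)
        assert np.array_equal(a.delta, b.delta) and np.array_equal(a.pi, b.pi)

    def test_globals_recovered(self, small_fit):
        draws, truth, *_ = small_fit
        assert abs(draws.pi.mean() - 0.1) < 0.1
        assert abs(draws.p0.mean() - 0.8) < 0.1

    def test_null_simulation_calls_almost_nothing(self):
        """With no TE change anywhere the model stays quiet."""
        cfg = SimConfig(
            n_genes=200, times=(0, 12), lib_depth=200_000.0, p0=1.0,
            sigma_pair=0.05, lib_size_sd=0.1, seed=17,
        )
        cm, _ = fitted_matrix(cfg)
        spec = ModelSpec(n_chains=1, n_iter=1000, n_burnin=300, thin=2, seed=31)
        draws = fit_mcmc(cm, spec)
        q = posterior_change_prob(draws, 2.0)
        assert q.median() < 0.5
        sel, _ = bayesian_fdr_select(q.to_numpy(), 0.05)
        assert sel.mean() <= 0.05

    def test_missing_size_factors_rejected(self):
        cm, _ = simulate_counts(SimConfig(n_genes=20, times=(0, 12), seed=1))
        cm = drop_all_zero_genes(cm)
        with pytest.raises(ValueError, match="size factors"):
            fit_mcmc(cm, ModelSpec(n_iter=10, n_burnin=5, seed=0))


class TestSummarize:
    def test_row_count_and_uncalled_spike_gene(self):
        cfg = SimConfig(
            n_genes=80, times=(0, 12), lib_depth=100_000.0, seed=23,
            sigma_pair=0.05, lib_size_sd=0.05,
        )
        cm, truth = fitted_matrix(cfg)
        spec = ModelSpec(n_chains=1, n_iter=600, n_burnin=200, thin=2, seed=7)
        draws = fit_mcmc(cm, spec)
        tab = summarize(draws)
        assert len(tab) == len(cm.genes)
        assert set(tab.columns) >= {"delta_mean", "delta_lo", "delta_hi", "q", "called"}
        assert ((tab["q"] >= 0) & (tab["q"] <= 1)).all()

    def test_all_spike_draws_give_unit_interval(self):
        from tests.test_model import TestPosteriorChangeProb

        d = TestPosteriorChangeProb().make_draws([1.0] * 20, [0] * 20)
        tab = summarize(d)
        row = tab.iloc[0]
        assert row["delta_mean"] == 1.0
        assert (row["delta_lo"], row["delta_hi"]) == (1.0, 1.0)
        assert not row["called"]


class TestDiagnostics:
    def test_single_chain_rejected(self):
        from tests.test_model import TestPosteriorChangeProb

        d = TestPosteriorChangeProb().make_draws([1.0] * 5, [0] * 5)
        with pytest.raises(ValueError):
            convergence_diagnostics(d)

    def test_constant_chains_flagged(self):
        from ribote.model import PosteriorDraws

        K = 50
        d = PosteriorDraws(
            gene_ids=["g"], delta=np.ones((2, K, 1)), z=np.zeros((2, K, 1), np.int8),
            log_mu=np.zeros((2, K, 1)), log_rho=np.zeros((2, K, 1, 1)),
            eta=np.zeros((2, K, 1)), pi=np.full((2, K), 0.1),
            p0=np.full((2, K), 0.9), sigma_pair=np.zeros((2, K)),
            acceptance={}, later_times=[12], contrast_time=12, spec=ModelSpec(),
        )
        diag = convergence_diagnostics(d)
        assert diag["flagged"].all()

    def test_well_mixed_run_converges(self):
        cfg = SimConfig(
            n_genes=60, times=(0, 12), lib_depth=60_000.0, seed=29,
            sigma_pair=0.05, lib_size_sd=0.05,
        )
        cm, _ = fitted_matrix(cfg)
        spec = ModelSpec(n_chains=2, n_iter=2500, n_burnin=500, thin=2, seed=77)
        draws = fit_mcmc(cm, spec)
        diag = convergence_diagnostics(draws)
        globals_ = diag[diag["parameter"].isin(["pi", "p0", "sigma_pair"])]
        assert (globals_["rhat"] < 1.1).all()
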