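"""Gibbs sweep full conditionals and the MCMC driver."""

import numpy as np
import pytest

from csprs.errors import ConfigurationError, NumericalError
from csprs.gibbs import (
    GibbsState,
    MCMCConfig,
    PriorConfig,
    run_mcmc,
    update_beta,
    update_phi_auto,
    update_psi_delta,
    update_sigma2,
)


def _frozen_state(p, psi=1.0, sigma2=1.0, phi=1.0, beta=None, delta=1.0):
    s = GibbsState.initial(p, phi=phi)
    s.psi = np.full(p, float(psi))
    s.delta = np.full(p, float(delta))
    s.sigma2 = float(sigma2)
    if beta is not None:
        s.beta = np.asarray(beta, dtype=float)
    return s


class TestUpdateBeta:
    def test_identity_ld_unit_psi_mean_is_half(self):
        """D=I, psi=1: conditional mean is beta_hat/2 elementwise."""
        p, n, n_draw = 5, 10_000, 4000
        beta_hat = np.array([0.02, -0.01, 0.0, 0.005, 0.03])
        rng = np.random.default_rng(20)
        state = _frozen_state(p)
        idx = np.arange(p)
        draws = np.array([update_beta(state, np.eye(p), beta_hat, idx, n, rng)
                          for _ in range(n_draw)])
        # Var of each draw is (sigma2/n) * (1/2); draws are iid given frozen scales.
        se = np.sqrt((1.0 / n) * 0.5 / n_draw)
        assert np.all(np.abs(draws.mean(axis=0) - beta_hat / 2.0) < 3 * se)

    def test_zero_beta_hat_symmetric_about_zero(self):
        p, n = 3, 5000
        rng = np.random.default_rng(21)
        state = _frozen_state(p)
        idx = np.arange(p)
        draws = np.array([update_beta(state, np.eye(p), np.zeros(p), idx, n, rng)
                          for _ in range(3000)])
        se = np.sqrt((1.0 / n) * 0.5 / 3000)
        assert np.all(np.abs(draws.mean(axis=0)) < 3 * se)

    def test_two_snp_conditional_mean_and_cov(self):
        """Empirical mean/cov match A^-1 beta_hat and (sigma2/n) A^-1 from a
        direct 2x2 matrix-inverse oracle."""
        D = np.array([[1.0, 0.5], [0.5, 1.0]])
        beta_hat = np.array([0.1, 0.0])
        n = 1000
        A = D + np.eye(2)
        mean_oracle = np.linalg.solve(A, beta_hat)  # = (0.0533..., -0.0133...)
        cov_oracle = np.linalg.inv(A) / n
        assert mean_oracle == pytest.approx([8.0 / 150.0, -2.0 / 150.0])

        rng = np.random.default_rng(22)
        state = _frozen_state(2)
        idx = np.arange(2)
        draws = np.array([update_beta(state, D, beta_hat, idx, n, rng)
                          for _ in range(20_000)])
        se = np.sqrt(np.diag(cov_oracle) / len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - mean_oracle) < 3 * se)
        emp_cov = np.cov(draws.T)
        assert np.allclose(emp_cov, cov_oracle, atol=4 * cov_oracle[0, 0] / np.sqrt(len(draws)) * 10)

    def test_near_singular_block_gets_jitter(self):
        """A duplicated SNP makes D singular; jitter keeps the draw finite."""
        D = np.ones((2, 2))  # rank one
        state = _frozen_state(2, psi=1e12)  # diag(1/psi) ~ 0: A nearly singular
        rng = np.random.default_rng(23)
        draw = update_beta(state, D, np.array([0.01, 0.01]), np.arange(2), 1000, rng)
        assert np.all(np.isfinite(draw))


class TestUpdateSigma2:
    def test_zero_beta_rate_is_n_over_2(self):
        """beta=0: e=n/2 and E[1/sigma2]=(n+p)/n."""
        p, n = 4, 200
        state = _frozen_state(p, beta=np.zeros(p))
        blocks = [(np.arange(p), np.eye(p))]
        rng = np.random.default_rng(24)
        n_draw = 100_000
        inv = np.empty(n_draw)
        for i in range(n_draw):
            inv[i] = 1.0 / update_sigma2(state, np.zeros(p), blocks, n, rng)
        shape, rate = (n + p) / 2.0, n / 2.0
        exp_mean = shape / rate
        se = np.sqrt(shape / rate**2 / n_draw)
        assert abs(inv.mean() - exp_mean) < 3 * se

    def test_two_snp_state_matches_arithmetic_oracle(self):
        """Rate e from scalar arithmetic; empirical mean of 1/sigma2 = shape/e."""
        n = 500
        D = np.array([[1.0, 0.3], [0.3, 1.0]])
        beta = np.array([0.05, -0.02])
        psi = np.array([0.5, 0.25])
        beta_hat = np.array([0.04, -0.01])
        # Scalar oracle for e:
        quad = (
            beta[0] ** 2 * D[0, 0] + beta[1] ** 2 * D[1, 1]
            + 2 * beta[0] * beta[1] * D[0, 1]
            + beta[0] ** 2 / psi[0] + beta[1] ** 2 / psi[1]
        )
        lin = beta[0] * beta_hat[0] + beta[1] * beta_hat[1]
        ridge = beta[0] ** 2 / psi[0] + beta[1] ** 2 / psi[1]
        e_oracle = max((n / 2) * (1 - 2 * lin + quad), (n / 2) * ridge)
        assert e_oracle > 0

        state = _frozen_state(2, beta=beta)
        state.psi = psi
        rng = np.random.default_rng(25)
        n_draw = 50_000
        inv = np.empty(n_draw)
        for i in range(n_draw):
            inv[i] = 1.0 / update_sigma2(state, beta_hat, [(np.arange(2), D)], n, rng)
        shape = (n + 2) / 2.0
        se = np.sqrt(shape / e_oracle**2 / n_draw)
        assert abs(inv.mean() - shape / e_oracle) < 3 * se

    def test_positive_rate_guard(self):
        """The max(...) guard keeps e > 0 for any nonzero beta."""
        n = 100
        beta = np.array([1e-3, -1e-3])
        # Adversarial beta_hat that would make the quadratic expression negative.
        state = _frozen_state(2, beta=beta)
        rng = np.random.default_rng(26)
        s2 = update_sigma2(state, np.array([10.0, 10.0]), [(np.arange(2), np.eye(2))], n, rng)
        assert s2 > 0 and np.isfinite(s2)


class TestUpdatePsiDelta:
    def test_delta_conjugate_mean(self):
        """delta | psi=0.5, phi=1, a=1, b=0.5 ~ Gamma(1.5, rate 1.5): mean 1."""
        p = 100_000
        prior = PriorConfig(a=1.0, b=0.5, phi=1.0)
        state = _frozen_state(p, phi=1.0, beta=np.full(p, 0.01), sigma2=1.0)
        rng = np.random.default_rng(27)
        psi, delta = update_psi_delta(state, n=10_000, prior=prior, rng=rng)
        # Conditional mean given each drawn psi: (a+b)/(psi+phi).
        cond_mean = 1.5 / (psi + 1.0)
        cond_var = 1.5 / (psi + 1.0) ** 2
        se = np.sqrt(cond_var.mean() / p)
        assert abs((delta - cond_mean).mean()) < 3 * se

    def test_psi_zero_beta_matches_capped_gamma_oracle(self):
        """beta=0, a=1: psi ~ min(Gamma(1/2, rate delta), 1); Monte-Carlo oracle."""
        p = 100_000
        prior = PriorConfig(a=1.0, b=0.5, phi=1.0)
        delta0 = 0.7
        state = _frozen_state(p, beta=np.zeros(p), delta=delta0)
        rng = np.random.default_rng(28)
        psi, _ = update_psi_delta(state, n=10_000, prior=prior, rng=rng)
        oracle_rng = np.random.default_rng(29)
        oracle = np.minimum(oracle_rng.gamma(0.5, 1.0 / delta0, size=500_000), 1.0)
        se = np.sqrt(oracle.var() / p + oracle.var() / len(oracle))
        assert abs(psi.mean() - oracle.mean()) < 3 * se

    def test_psi_always_capped_at_one(self):
        p = 2000
        prior = PriorConfig()
        state = _frozen_state(p, beta=np.full(p, 0.5), sigma2=0.01, delta=1e-6)
        rng = np.random.default_rng(30)
        psi, delta = update_psi_delta(state, n=100_000, prior=prior, rng=rng)
        assert np.all(psi <= 1.0) and np.all(psi > 0) and np.all(delta > 0)


class TestUpdatePhi:
    def test_phi_stays_positive(self):
        prior = PriorConfig()
        state = _frozen_state(50, delta=0.5)
        rng = np.random.default_rng(31)
        for _ in range(10_000):
            phi = update_phi_auto(state, prior, rng)
            assert phi > 0

    def test_conditional_moment_with_large_delta(self):
        """With large fixed deltas, E[phi] ~ (p*b + 1/2)/sum(delta)."""
        p, b = 200, 0.5
        prior = PriorConfig(a=1.0, b=b, phi="auto")
        delta_val = 50.0
        rng = np.random.default_rng(32)
        draws = np.empty(20_000)
        for i in range(len(draws)):
            state = _frozen_state(p, delta=delta_val, phi=1.0)
            draws[i] = update_phi_auto(state, prior, rng)
        shape = p * b + 0.5
        rate = p * delta_val  # w << sum(delta), negligible
        se = np.sqrt(shape / rate**2 / len(draws))
        assert abs(draws.mean() - shape / rate) < 3 * se + shape / rate * 1e-2

    def test_fixed_phi_constant_through_run(self, small_study):
        w = run_mcmc(
            small_study["harm"], small_study["ref"],
            PriorConfig(phi=0.01),
            MCMCConfig(n_iter=40, n_burnin=20, thin=2, seed=3),
        )
        assert w.phi_mean == pytest.approx(0.01)


class TestRunMcmc:
    def test_seed_determinism_bit_identical(self, small_study):
        mcmc = MCMCConfig(n_iter=60, n_burnin=30, thin=3, seed=42)
        w1 = run_mcmc(small_study["harm"], small_study["ref"], PriorConfig(), mcmc)
        w2 = run_mcmc(small_study["harm"], small_study["ref"], PriorConfig(), mcmc)
        np.testing.assert_array_equal(w1.beta, w2.beta)
        assert w1.phi_mean == w2.phi_mean and w1.sigma2_mean == w2.sigma2_mean

    def test_different_seeds_differ(self, small_study):
        w1 = run_mcmc(small_study["harm"], small_study["ref"], PriorConfig(),
                      MCMCConfig(n_iter=60, n_burnin=30, thin=3, seed=1))
        w2 = run_mcmc(small_study["harm"], small_study["ref"], PriorConfig(),
                      MCMCConfig(n_iter=60, n_burnin=30, thin=3, seed=2))
        assert not np.array_equal(w1.beta, w2.beta)

    def test_parallel_equals_sequential(self, small_study):
        mcmc = MCMCConfig(n_iter=50, n_burnin=25, thin=5, seed=7)
        seq = run_mcmc(small_study["harm"], small_study["ref"], PriorConfig(), mcmc, n_jobs=1)
        par = run_mcmc(small_study["harm"], small_study["ref"], PriorConfig(), mcmc, n_jobs=2)
        np.testing.assert_array_equal(seq.beta, par.beta)

    def test_shrinkage_monotone_in_phi(self, small_study):
        """Smaller fixed phi shrinks harder: mean |beta_post| decreases."""
        means = []
        for phi in (1e-4, 1e2):
            reps = []
            for seed in (5, 6):
                w = run_mcmc(small_study["harm"], small_study["ref"],
                             PriorConfig(phi=phi),
                             MCMCConfig(n_iter=120, n_burnin=60, thin=3, seed=seed))
                reps.append(np.mean(np.abs(w.beta)))
            means.append(np.mean(reps))
        assert means[0] < means[1]

    def test_per_allele_rescaling(self, small_study):
        mcmc = MCMCConfig(n_iter=40, n_burnin=20, thin=2, seed=9)
        std = run_mcmc(small_study["harm"], small_study["ref"], PriorConfig(), mcmc,
                       beta_scale="standardized")
        pa = run_mcmc(small_study["harm"], small_study["ref"], PriorConfig(), mcmc,
                      beta_scale="per-allele")
        tab = small_study["harm"].table.set_index("snp_id")
        maf = tab.loc[std.table["SNP"], "maf"].to_numpy()
        np.testing.assert_allclose(pa.beta, std.beta / np.sqrt(2 * maf * (1 - maf)),
                                   rtol=1e-12)

    def test_output_snp_set_matches_input(self, small_study):
        w = run_mcmc(small_study["harm"], small_study["ref"], PriorConfig(),
                     MCMCConfig(n_iter=30, n_burnin=10, thin=2, seed=0))
        assert set(w.table["SNP"]) == set(small_study["harm"].table["snp_id"])
        assert np.all(np.isfinite(w.beta))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            MCMCConfig(n_iter=10, n_burnin=10)
        with pytest.raises(ConfigurationError):
            PriorConfig(a=-1.0)
        with pytest.raises(ConfigurationError):
            PriorConfig(phi=0.0)

    def test_factorization_failure_names_block(self):
        from csprs.gibbs import _chol_with_jitter

        bad = np.array([[1.0, 0.0], [0.0, -5.0]])  # stays indefinite under jitter
        with pytest.raises(NumericalError, match="block"):
            _chol_with_jitter(bad, "block 0")
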