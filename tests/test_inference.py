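"""Adaptive Metropolis sampler, Gelman-Rubin diagnostic, posterior
predictive machinery."""

import numpy as np
import pytest
from scipy.stats import chi2, kstest

from spikemeta.inference import (MCMCConfig, PosteriorSamples,
                                 adaptive_metropolis, gelman_rubin,
                                 log_posterior, posterior_predictive)
from spikemeta.parameters import ParameterDomain


def _gaussian_target(d=10, seed=5):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((d, d))
    cov = a @ a.T + d * np.eye(d)
    mu = rng.uniform(-2, 2, d)
    prec = np.linalg.inv(cov)

    def lp(th):
        r = th - mu
        return -0.5 * r @ prec @ r

    return lp, mu, cov, rng


@pytest.fixture(scope="module")
def gaussian_run():
    lp, mu, cov, rng = _gaussian_target()
    config = MCMCConfig(n_chains=5, n_proposals=40_000, n_burn_in=12_000,
                        seed=1)
    init = rng.multivariate_normal(mu, cov, size=5)
    samples = adaptive_metropolis(lp, config, init)
    return samples, mu, cov


class TestLogPosterior:
    class FlatModel:
        def log_prob(self, theta, x):
            return 0.0

    def test_outside_box_minus_infinity(self):
        dom = ParameterDomain()
        theta = dom.lower.copy()
        theta[3] = dom.upper[3] + 1.0
        assert log_posterior(self.FlatModel(), np.zeros(3), theta, dom) == -np.inf

    def test_prior_constant_cancels_in_differences(self):
        dom = ParameterDomain()

        class Quad:
            def log_prob(self, theta, x):
                return -float(np.sum(theta ** 2))

        model = Quad()
        mid = 0.5 * (dom.lower + dom.upper)
        other = mid + 0.01 * (dom.upper - dom.lower)
        x0 = np.zeros(2)
        diff = (log_posterior(model, x0, mid, dom)
                - log_posterior(model, x0, other, dom))
        assert diff == pytest.approx(model.log_prob(mid, x0)
                                     - model.log_prob(other, x0))


class TestAdaptiveMetropolis:
    def test_gaussian_target_recovered(self, gaussian_run):
        samples, mu, cov = gaussian_run
        pooled = samples.pooled()
        # conservative effective-sample-size-aware check on the means
        import arviz as az
        ess = np.array([az.ess(samples.draws[:, :, i]) for i in range(10)])
        se = np.sqrt(np.diag(cov) / ess)
        assert np.all(np.abs(pooled.mean(0) - mu) < 3 * se)
        emp = np.cov(pooled.T)
        assert np.linalg.norm(emp - cov) / np.linalg.norm(cov) < 0.10

    def test_tuned_acceptance_near_target(self, gaussian_run):
        samples, _, _ = gaussian_run
        assert 0.2 < samples.acceptance.mean() < 0.45
        assert np.all(samples.acceptance > 0) and np.all(samples.acceptance < 1)

    def test_convergence_diagnostic_attached(self, gaussian_run):
        samples, _, _ = gaussian_run
        assert samples.r_hat.shape == (10,)
        assert np.all(samples.r_hat < 1.1)

    def test_flat_target_marginals_uniform(self):
        lo, hi = np.zeros(3), np.ones(3)

        def lp(th):
            return 0.0 if np.all((th >= lo) & (th <= hi)) else -np.inf

        config = MCMCConfig(n_chains=4, n_proposals=20_000, n_burn_in=5_000,
                            seed=2)
        init = np.random.default_rng(3).uniform(0.2, 0.8, (4, 3))
        samples = adaptive_metropolis(lp, config, init)
        thinned = samples.pooled()[::50]
        for i in range(3):
            stat = kstest(thinned[:, i], "uniform").statistic
            # 1% critical value of the one-sample KS statistic
            crit = 1.63 / np.sqrt(len(thinned))
            assert stat < crit

    def test_detailed_balance_on_2d_gaussian(self):
        lp2, mu2, cov2, rng = _gaussian_target(d=2, seed=9)
        config = MCMCConfig(n_chains=2, n_proposals=30_000, n_burn_in=8_000,
                            seed=4)
        init = rng.multivariate_normal(mu2, cov2, size=2)
        samples = adaptive_metropolis(lp2, config, init)
        chain = samples.draws[0]
        # coarse-bin the first coordinate and test transition symmetry
        edges = np.quantile(chain[:, 0], [0.25, 0.5, 0.75])
        states = np.digitize(chain[:, 0], edges)
        pairs = np.column_stack([states[:-1], states[1:]])
        stat, dof = 0.0, 0
        for i in range(4):
            for j in range(i + 1, 4):
                nij = np.sum((pairs[:, 0] == i) & (pairs[:, 1] == j))
                nji = np.sum((pairs[:, 0] == j) & (pairs[:, 1] == i))
                if nij + nji > 0:
                    stat += (nij - nji) ** 2 / (nij + nji)
                    dof += 1
        assert chi2.sf(stat, dof) > 0.01

    def test_reproducible_under_seed(self):
        lp, mu, cov, rng = _gaussian_target(d=3, seed=0)
        config = MCMCConfig(n_chains=2, n_proposals=2_000, n_burn_in=500,
                            seed=7)
        init = rng.multivariate_normal(mu, cov, size=2)
        a = adaptive_metropolis(lp, config, init)
        b = adaptive_metropolis(lp, config, init)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_proposals=100, n_burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)


class TestGelmanRubin:
    def test_common_distribution_converged(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((4, 2000, 3))
        r = gelman_rubin(PosteriorSamples(draws=draws, acceptance=np.ones(4),
                                          proposal_cov=np.zeros(0),
                                          proposal_scale=np.zeros(0)))
        assert np.all(r < 1.1)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((3, 500, 2))
        draws[1] += 10.0
        r = gelman_rubin(PosteriorSamples(draws=draws, acceptance=np.ones(3),
                                          proposal_cov=np.zeros(0),
                                          proposal_scale=np.zeros(0)))
        assert np.all(r > 1.2)

    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(2)
        one = rng.standard_normal((1, 1000, 2))
        draws = np.concatenate([one, one], axis=0)
        r = gelman_rubin(PosteriorSamples(draws=draws, acceptance=np.ones(2),
                                          proposal_cov=np.zeros(0),
                                          proposal_scale=np.zeros(0)))
        assert np.all(np.abs(r - 1.0) < 0.05)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(PosteriorSamples(
                draws=np.zeros((1, 100, 2)), acceptance=np.ones(1),
                proposal_cov=np.zeros(0), proposal_scale=np.zeros(0)))

    def test_cross_check_against_arviz(self):
        import arviz as az
        rng = np.random.default_rng(3)
        draws = rng.standard_normal((4, 800, 2))
        draws[:, :, 1] += np.linspace(0, 0.5, 4)[:, None]  # mild shift
        ours = gelman_rubin(PosteriorSamples(
            draws=draws, acceptance=np.ones(4), proposal_cov=np.zeros(0),
            proposal_scale=np.zeros(0)))
        ref = np.array([float(az.rhat(draws[:, :, i])) for i in range(2)])
        # arviz rank-normalizes; agreement is approximate
        np.testing.assert_allclose(ours, ref, atol=0.05)


class TestPosteriorPredictive:
    @staticmethod
    def _point_mass_samples(theta, d=3):
        draws = np.tile(theta, (2, 100, 1))
        return PosteriorSamples(draws=draws, acceptance=np.full(2, 0.3),
                                proposal_cov=np.zeros(0),
                                proposal_scale=np.zeros(0))

    def test_point_mass_posterior_gives_replicate_variability(self):
        rng = np.random.default_rng(0)
        theta_true = np.array([0.2, 0.4, 0.6])
        x0 = rng.standard_normal(20)

        def sim(theta, seed):
            noise = np.random.default_rng(seed).normal(0, 0.05, 20)
            return x0 + noise

        samples = self._point_mass_samples(theta_true)
        _, spectra, dists, worst = posterior_predictive(samples, 20, sim, x0,
                                                        seed=1)
        # distances reflect only seed-to-seed variability of the simulator
        assert np.all(dists < 0.05 * 5)
        assert worst == dists.max()

    def test_empty_draw_request(self):
        samples = self._point_mass_samples(np.zeros(3))
        thetas, spectra, dists, worst = posterior_predictive(
            samples, 0, lambda t, s: np.zeros(4), np.zeros(4))
        assert len(thetas) == 0 and len(dists) == 0 and np.isnan(worst)

    def test_distance_permutation_invariant(self):
        rng = np.random.default_rng(1)
        x0 = rng.standard_normal(30)
        perm = rng.permutation(30)
        samples = self._point_mass_samples(np.zeros(3))

        def sim(theta, seed):
            return x0 + np.random.default_rng(seed).normal(0, 0.1, 30)

        _, _, d1, w1 = posterior_predictive(samples, 10, sim, x0, seed=2)

        def sim_perm(theta, seed):
            return sim(theta, seed)[perm]

        _, _, d2, w2 = posterior_predictive(samples, 10, sim_perm, x0[perm],
                                            seed=2)
        np.testing.assert_allclose(d1, d2)
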