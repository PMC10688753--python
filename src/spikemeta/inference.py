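"""Posterior sampling over network parameters with adaptive Metropolis.

The posterior is ``p(theta | x0) ∝ p(x0 | theta) p(theta)`` with a uniform
prior over the parameter box and the metamodel supplying the surrogate
likelihood.  Sampling uses a Gaussian random-walk Metropolis whose proposal
covariance is iteratively estimated from the chain history during the burn-in
phase only and then frozen; a separate scalar factor is tuned during burn-in
by log-scale stochastic approximation toward a target acceptance ratio of
0.3.  Five chains of 40000 proposals with a 12000-proposal burn-in are the
defaults; convergence is diagnosed per parameter with the (split-chain)
Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "MCMCConfig", "PosteriorSamples", "log_posterior", "adaptive_metropolis",
    "gelman_rubin", "posterior_predictive",
]


@dataclass
class MCMCConfig:
    n_chains: int = 5
    n_proposals: int = 40000          # per chain
    n_burn_in: int = 12000
    target_acceptance: float = 0.3
    adapt_start: int = 500            # proposals before covariance adaptation
    adapt_interval: int = 100         # recompute covariance every this many
    seed: int = 0

    def __post_init__(self):
        if self.n_burn_in >= self.n_proposals:
            raise ValueError("burn-in must be shorter than the chain")
        if self.n_chains < 2:
            raise ValueError("at least two chains are required for the "
                             "Gelman-Rubin diagnostic")


@dataclass
class PosteriorSamples:
    """Post-burn-in draws with acceptance and convergence metadata."""

    draws: np.ndarray                # (chains, iterations, d)
    acceptance: np.ndarray           # per chain, post burn-in
    proposal_cov: np.ndarray         # (chains, d, d) frozen covariances
    proposal_scale: np.ndarray       # per chain frozen scalar factor
    r_hat: Optional[np.ndarray] = None
    x0: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def d(self) -> int:
        return self.draws.shape[2]

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.d)

    def mean(self) -> np.ndarray:
        return self.pooled().mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.pooled().std(axis=0, ddof=1)


def log_posterior(model, x0: np.ndarray, theta: np.ndarray, domain) -> float:
    """Log posterior: surrogate log-likelihood plus log uniform prior.

    Returns -inf outside the prior box (a value, not an error); inside, the
    prior contributes a constant -sum(log(range)).
    """
    theta = np.asarray(theta, float)
    if not domain.contains(theta)[0]:
        return -np.inf
    log_prior = -float(np.sum(np.log(domain.upper - domain.lower)))
    return model.log_prob(theta, x0) + log_prior


def adaptive_metropolis(log_post: Callable[[np.ndarray], float],
                        config: MCMCConfig,
                        init: np.ndarray,
                        init_proposal_sd: Optional[np.ndarray] = None,
                        x0: Optional[np.ndarray] = None) -> PosteriorSamples:
    """Run adaptive Metropolis chains on an arbitrary log-density.

    ``init`` is (n_chains, d) initial states (must have finite log-density).
    During burn-in the proposal covariance is re-estimated from the chain's
    own history (diagonal fallback before ``adapt_start`` proposals) and a
    scalar factor is tuned toward the target acceptance ratio; both are
    frozen at the end of burn-in.  Draws returned are post-burn-in only, with
    no thinning.
    """
    init = np.atleast_2d(np.asarray(init, float))
    n_chains, d = init.shape
    if n_chains != config.n_chains:
        raise ValueError("init must supply one start point per chain")
    rng = np.random.default_rng(config.seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=n_chains)

    n_keep = config.n_proposals - config.n_burn_in
    draws = np.empty((n_chains, n_keep, d))
    acceptance = np.empty(n_chains)
    frozen_cov = np.empty((n_chains, d, d))
    frozen_scale = np.empty(n_chains)

    if init_proposal_sd is None:
        spread = init.std(axis=0)
        init_proposal_sd = np.where(spread > 0, 0.1 * spread, 0.1)

    for c in range(n_chains):
        crng = np.random.default_rng(int(chain_seeds[c]))
        theta = init[c].copy()
        lp = log_post(theta)
        if not np.isfinite(lp):
            raise ValueError("initial point has non-finite log-density")
        cov = np.diag(np.asarray(init_proposal_sd, float) ** 2)
        chol = np.linalg.cholesky(cov)
        log_scale = np.log(2.38 / np.sqrt(d))
        history = np.empty((config.n_proposals, d))
        n_acc_post = 0
        n_burn_acc = 0
        for t in range(config.n_proposals):
            adapting = t < config.n_burn_in
            step = np.exp(log_scale) * (chol @ crng.standard_normal(d))
            prop = theta + step
            lp_prop = log_post(prop)
            accept = np.log(crng.uniform()) < lp_prop - lp
            if accept:
                theta = prop
                lp = lp_prop
            history[t] = theta
            if adapting:
                if accept:
                    n_burn_acc += 1
                # Robbins-Monro tuning of the scalar factor
                gamma = 1.0 / (1.0 + t) ** 0.6
                log_scale += gamma * (float(accept) - config.target_acceptance)
                if (t + 1 >= config.adapt_start
                        and (t + 1) % config.adapt_interval == 0):
                    sample_cov = np.cov(history[: t + 1].T)
                    sample_cov = np.atleast_2d(sample_cov)
                    sample_cov += 1e-10 * np.eye(d)
                    try:
                        chol = np.linalg.cholesky(sample_cov)
                        cov = sample_cov
                    except np.linalg.LinAlgError:
                        pass
            else:
                if accept:
                    n_acc_post += 1
        if n_burn_acc == 0:
            raise RuntimeError(
                "no proposal accepted during burn-in (degenerate target); "
                f"chain {c}, last log-density {lp}")
        draws[c] = history[config.n_burn_in:]
        acceptance[c] = n_acc_post / n_keep
        frozen_cov[c] = cov
        frozen_scale[c] = np.exp(log_scale)

    samples = PosteriorSamples(
        draws=draws, acceptance=acceptance, proposal_cov=frozen_cov,
        proposal_scale=frozen_scale, x0=None if x0 is None else np.asarray(x0),
        meta={"n_proposals": config.n_proposals,
              "n_burn_in": config.n_burn_in,
              "total_proposals": config.n_proposals * n_chains})
    samples.r_hat = gelman_rubin(samples)
    return samples


def gelman_rubin(samples: PosteriorSamples, split: bool = True) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    Compares between- and within-chain variances; by default each chain is
    split in half (robust against within-chain trends), the plain variant is
    available with ``split=False``.
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    if draws.ndim != 3:
        raise ValueError("draws must be (chains, iterations, parameters)")
    m, n, d = draws.shape
    if m < 2:
        raise ValueError("at least two chains are required")
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    if split:
        half = n // 2
        draws = np.concatenate([draws[:, :half], draws[:, half: 2 * half]],
                               axis=0)
        m, n = 2 * m, half
    chain_means = draws.mean(axis=1)                    # (m, d)
    chain_vars = draws.var(axis=1, ddof=1)              # (m, d)
    w = chain_vars.mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_hat / w)
    return r


def posterior_predictive(samples: PosteriorSamples, n_draws: int,
                         simulate_spectrum: Callable[[np.ndarray, int], np.ndarray],
                         x0: np.ndarray, seed: int = 0):
    """Simulate from posterior draws and measure spectral distances.

    ``simulate_spectrum(theta, seed)`` must run the simulator pipeline and
    return a log10 spectrum on the same grid as the conditioning output
    ``x0``.  Returns (drawn thetas, simulated spectra, per-draw max abs
    distances, max distance over all draws), the last being the
    max-over-frequencies-and-draws statistic.
    """
    if n_draws == 0:
        return (np.zeros((0, samples.d)), np.zeros((0, len(x0))),
                np.zeros(0), np.nan)
    rng = np.random.default_rng(seed)
    pooled = samples.pooled()
    idx = rng.integers(0, len(pooled), size=n_draws)
    thetas = pooled[idx]
    spectra = []
    dists = []
    x0 = np.asarray(x0, float)
    for i, theta in enumerate(thetas):
        spec = simulate_spectrum(theta, int(rng.integers(0, 2**31 - 1)))
        spectra.append(spec)
        dists.append(float(np.max(np.abs(spec - x0))))
    spectra = np.asarray(spectra)
    dists = np.asarray(dists)
    return thetas, spectra, dists, float(dists.max())
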