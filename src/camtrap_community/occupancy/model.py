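"""Metropolis-within-Gibbs sampler for the community occupancy model.

Model, for species i at site j:

    z[i,j]        ~ Bernoulli(psi[i,j]),   logit psi = X[j] . alpha[i]
    y[i,j] | z    ~ Binomial(K[j], z[i,j] * p[i,j]),  logit p = W[j] . beta[i]
    alpha[i,k]    ~ Normal(mu_occ[k], sd_occ[k]^2)    (community hyper-prior)
    beta[i,k]     ~ Normal(mu_det[k], sd_det[k]^2)
    mu_*          ~ Normal(0, 10^2),  sd_* ~ Uniform(0, 10)

Updates: z from its exact Bernoulli full conditional; species
coefficients by adaptive random-walk Metropolis (one coefficient column
at a time, vectorized across species — the likelihood factorizes over
species so per-species accept/reject is valid); hyper-means by their
conjugate normal conditional; hyper-sds by random walk on the log scale.
Proposal scales adapt during burn-in only, so the post-burn-in chain is
a valid fixed-kernel Markov chain. Seeded runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from camtrap_community.occupancy.design import DesignMatrix
from camtrap_community.occupancy.diagnostics import ConvergenceReport, convergence_report
from camtrap_community.occupancy.history import DetectionHistory

logger = logging.getLogger(__name__)

_TARGET_ACCEPT = 0.44
_ADAPT_BATCH = 50


@dataclass(frozen=True)
class PriorConfig:
    """Conventional vague community-model priors; fully configurable."""

    hierarchical: bool = True
    hyper_mean_sd: float = 10.0  # mu_k ~ Normal(0, hyper_mean_sd^2)
    hyper_sd_upper: float = 10.0  # sd_k ~ Uniform(0, hyper_sd_upper)
    coef_mean: float = 0.0  # fixed-prior mode: coef ~ Normal(coef_mean, coef_sd^2)
    coef_sd: float = 10.0


@dataclass(frozen=True)
class MCMCConfig:
    """`iterations` is the total chain length including burn-in, so the
    stored draw count is chains x (iterations - burn_in) / thin."""

    chains: int = 3
    iterations: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("require 0 <= burn_in < iterations")
        if self.thin < 1 or (self.iterations - self.burn_in) % self.thin:
            raise ValueError("(iterations - burn_in) must be a multiple of thin")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @classmethod
    def desk_profile(cls, seed: int = 0) -> "MCMCConfig":
        return cls(chains=3, iterations=6000, burn_in=1000, thin=5, seed=seed)

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "MCMCConfig":
        # 50,000 kept iterations after 10,000 burn-in, thinned by 50
        return cls(chains=3, iterations=60000, burn_in=10000, thin=50, seed=seed)


@dataclass
class PosteriorSamples:
    species: list[str]
    sites: list[str]
    occ_columns: list[str]
    det_columns: list[str]
    alpha: np.ndarray  # (chains, draws, S, P_occ)
    beta: np.ndarray  # (chains, draws, S, P_det)
    z: np.ndarray  # (chains, draws, S, J) uint8
    mu_alpha: np.ndarray | None  # (chains, draws, P_occ); None in fixed-prior mode
    sd_alpha: np.ndarray | None
    mu_beta: np.ndarray | None
    sd_beta: np.ndarray | None
    config: MCMCConfig
    priors: PriorConfig
    convergence: ConvergenceReport | None = field(default=None)

    def monitored_chains(self) -> dict[str, np.ndarray]:
        """Community-level chains (or species coefficients in fixed-prior
        mode), keyed by parameter name, each (chains, draws)."""
        out: dict[str, np.ndarray] = {}
        if self.mu_alpha is not None:
            for block, cols, mu, sd in (
                ("occ", self.occ_columns, self.mu_alpha, self.sd_alpha),
                ("det", self.det_columns, self.mu_beta, self.sd_beta),
            ):
                for k, col in enumerate(cols):
                    out[f"{block}_mu[{col}]"] = mu[:, :, k]
                    out[f"{block}_sd[{col}]"] = sd[:, :, k]
        else:
            for block, cols, coef in (
                ("occ", self.occ_columns, self.alpha),
                ("det", self.det_columns, self.beta),
            ):
                for i, sp in enumerate(self.species):
                    for k, col in enumerate(cols):
                        out[f"{block}[{sp}][{col}]"] = coef[:, :, i, k]
        return out

    def hyper_mean_draws(self, block: str, column: str) -> np.ndarray:
        """Flattened draws of a community hyper-mean (or, in fixed-prior
        single-species mode, the species coefficient itself)."""
        cols = self.occ_columns if block == "occ" else self.det_columns
        k = cols.index(column)
        if self.mu_alpha is not None:
            arr = self.mu_alpha if block == "occ" else self.mu_beta
            return arr[:, :, k].ravel()
        coef = self.alpha if block == "occ" else self.beta
        if coef.shape[2] != 1:
            raise ValueError("fixed-prior community draws need a hierarchical fit")
        return coef[:, :, 0, k].ravel()


def _occ_loglik(eta: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-species Bernoulli log-likelihood: z*eta - log(1 + e^eta), summed over sites."""
    return (z * eta - np.logaddexp(0.0, eta)).sum(axis=1)


def _det_loglik(eta: np.ndarray, z: np.ndarray, y: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Per-species Binomial log-likelihood at occupied sites (binomial
    coefficient omitted; it cancels in Metropolis ratios)."""
    return (z * (y * eta - K[None, :] * np.logaddexp(0.0, eta))).sum(axis=1)


class _ChainState:
    def __init__(
        self,
        rng: np.random.Generator,
        y: np.ndarray,
        K: np.ndarray,
        X: np.ndarray,
        W: np.ndarray,
        priors: PriorConfig,
    ) -> None:
        S, J = y.shape
        self.rng = rng
        self.y, self.K, self.X, self.W = y, K, X, W
        self.priors = priors
        P, Q = X.shape[1], W.shape[1]
        self.alpha = rng.normal(0.0, 0.25, size=(S, P))
        self.beta = rng.normal(0.0, 0.25, size=(S, Q))
        self.z = np.where(y > 0, 1, rng.integers(0, 2, size=(S, J))).astype(float)
        self.mu_a = np.zeros(P)
        self.sd_a = np.ones(P)
        self.mu_b = np.zeros(Q)
        self.sd_b = np.ones(Q)
        self.eta_occ = self.alpha @ X.T
        self.eta_det = self.beta @ W.T
        # adaptive RW scales
        self.step_a = np.full((S, P), 0.5)
        self.step_b = np.full((S, Q), 0.5)
        self.step_sd_a = np.full(P, 0.4)
        self.step_sd_b = np.full(Q, 0.4)
        self.acc_a = np.zeros((S, P))
        self.acc_b = np.zeros((S, Q))
        self.acc_sd_a = np.zeros(P)
        self.acc_sd_b = np.zeros(Q)

    # -- updates ---------------------------------------------------------
    def update_z(self) -> None:
        psi = expit(self.eta_occ)
        p = expit(self.eta_det)
        miss = np.power(1.0 - p, self.K[None, :])  # P(no detection in K occasions)
        num = psi * miss
        pz = num / (num + (1.0 - psi))
        draw = self.rng.random(size=self.y.shape)
        self.z = np.where(self.y > 0, 1.0, (draw < pz).astype(float))

    def _coef_prior_delta(
        self, prop: np.ndarray, cur: np.ndarray, mu: float, sd: float
    ) -> np.ndarray:
        return ((cur - mu) ** 2 - (prop - mu) ** 2) / (2.0 * sd**2)

    def update_alpha(self) -> None:
        S = self.alpha.shape[0]
        for k in range(self.alpha.shape[1]):
            cur = self.alpha[:, k]
            prop = cur + self.step_a[:, k] * self.rng.standard_normal(S)
            eta_new = self.eta_occ + (prop - cur)[:, None] * self.X[None, :, k]
            ll_new = _occ_loglik(eta_new, self.z)
            ll_old = _occ_loglik(self.eta_occ, self.z)
            if self.priors.hierarchical:
                mu, sd = self.mu_a[k], self.sd_a[k]
            else:
                mu, sd = self.priors.coef_mean, self.priors.coef_sd
            delta = ll_new - ll_old + self._coef_prior_delta(prop, cur, mu, sd)
            acc = np.log(self.rng.random(S)) < delta
            self.alpha[acc, k] = prop[acc]
            self.eta_occ[acc] = eta_new[acc]
            self.acc_a[:, k] += acc

    def update_beta(self) -> None:
        S = self.beta.shape[0]
        for k in range(self.beta.shape[1]):
            cur = self.beta[:, k]
            prop = cur + self.step_b[:, k] * self.rng.standard_normal(S)
            eta_new = self.eta_det + (prop - cur)[:, None] * self.W[None, :, k]
            ll_new = _det_loglik(eta_new, self.z, self.y, self.K)
            ll_old = _det_loglik(self.eta_det, self.z, self.y, self.K)
            if self.priors.hierarchical:
                mu, sd = self.mu_b[k], self.sd_b[k]
            else:
                mu, sd = self.priors.coef_mean, self.priors.coef_sd
            delta = ll_new - ll_old + self._coef_prior_delta(prop, cur, mu, sd)
            acc = np.log(self.rng.random(S)) < delta
            self.beta[acc, k] = prop[acc]
            self.eta_det[acc] = eta_new[acc]
            self.acc_b[:, k] += acc

    def _update_hyper(
        self, coef: np.ndarray, mu: np.ndarray, sd: np.ndarray,
        step_sd: np.ndarray, acc_sd: np.ndarray,
    ) -> None:
        S = coef.shape[0]
        pri = self.priors
        for k in range(coef.shape[1]):
            # conjugate normal update for mu_k (prior Normal(0, hyper_mean_sd^2))
            prec = S / sd[k] ** 2 + 1.0 / pri.hyper_mean_sd**2
            mean = (coef[:, k].sum() / sd[k] ** 2) / prec
            mu[k] = self.rng.normal(mean, np.sqrt(1.0 / prec))
            # log-scale RW for sd_k under Uniform(0, upper) prior (+ Jacobian)
            cur = sd[k]
            prop = cur * np.exp(step_sd[k] * self.rng.standard_normal())
            if prop < pri.hyper_sd_upper:
                ssq = ((coef[:, k] - mu[k]) ** 2).sum()
                delta = (
                    -S * np.log(prop) - ssq / (2.0 * prop**2)
                    + S * np.log(cur) + ssq / (2.0 * cur**2)
                    + np.log(prop) - np.log(cur)  # Jacobian of the log transform
                )
                if np.log(self.rng.random()) < delta:
                    sd[k] = prop
                    acc_sd[k] += 1

    def update_hypers(self) -> None:
        if not self.priors.hierarchical:
            return
        self._update_hyper(self.alpha, self.mu_a, self.sd_a, self.step_sd_a, self.acc_sd_a)
        self._update_hyper(self.beta, self.mu_b, self.sd_b, self.step_sd_b, self.acc_sd_b)

    def adapt(self, batch: int) -> None:
        gain = min(0.25, 1.0 / np.sqrt(batch))
        for acc, step in (
            (self.acc_a, self.step_a),
            (self.acc_b, self.step_b),
        ):
            rate = acc / _ADAPT_BATCH
            step *= np.exp(gain * (rate - _TARGET_ACCEPT))
            np.clip(step, 1e-3, 20.0, out=step)
            acc[:] = 0.0
        for acc, step in (
            (self.acc_sd_a, self.step_sd_a),
            (self.acc_sd_b, self.step_sd_b),
        ):
            rate = acc / _ADAPT_BATCH
            step *= np.exp(gain * (rate - _TARGET_ACCEPT))
            np.clip(step, 1e-3, 5.0, out=step)
            acc[:] = 0.0


def fit_community_occupancy(
    history: DetectionHistory,
    occ_design: DesignMatrix,
    det_design: DesignMatrix,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Sample the joint posterior of the community occupancy model.

    Returns samples with an attached convergence report; non-convergence
    (any monitored R-hat >= 1.1) is logged, not raised.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    if occ_design.sites != history.sites or det_design.sites != history.sites:
        raise ValueError("design sites must match detection-history sites (same order)")

    y = history.y.astype(float)
    K = history.K.astype(float)
    X, W = occ_design.X, det_design.X
    S, J = y.shape
    P, Q = X.shape[1], W.shape[1]
    n_draws = mcmc.draws_per_chain

    alpha = np.empty((mcmc.chains, n_draws, S, P))
    beta = np.empty((mcmc.chains, n_draws, S, Q))
    z = np.empty((mcmc.chains, n_draws, S, J), dtype=np.uint8)
    if priors.hierarchical:
        mu_a = np.empty((mcmc.chains, n_draws, P))
        sd_a = np.empty((mcmc.chains, n_draws, P))
        mu_b = np.empty((mcmc.chains, n_draws, Q))
        sd_b = np.empty((mcmc.chains, n_draws, Q))
    else:
        mu_a = sd_a = mu_b = sd_b = None

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    for c in range(mcmc.chains):
        state = _ChainState(np.random.default_rng(seeds[c]), y, K, X, W, priors)
        stored = 0
        batch = 0
        for it in range(mcmc.iterations):
            state.update_z()
            state.update_alpha()
            state.update_beta()
            state.update_hypers()
            if it < mcmc.burn_in:
                if (it + 1) % _ADAPT_BATCH == 0:
                    batch += 1
                    state.adapt(batch)
                continue
            if (it - mcmc.burn_in) % mcmc.thin == mcmc.thin - 1:
                alpha[c, stored] = state.alpha
                beta[c, stored] = state.beta
                z[c, stored] = state.z.astype(np.uint8)
                if priors.hierarchical:
                    mu_a[c, stored] = state.mu_a
                    sd_a[c, stored] = state.sd_a
                    mu_b[c, stored] = state.mu_b
                    sd_b[c, stored] = state.sd_b
                stored += 1
        assert stored == n_draws

    samples = PosteriorSamples(
        species=list(history.species),
        sites=list(history.sites),
        occ_columns=list(occ_design.columns),
        det_columns=list(det_design.columns),
        alpha=alpha,
        beta=beta,
        z=z,
        mu_alpha=mu_a,
        sd_alpha=sd_a,
        mu_beta=mu_b,
        sd_beta=sd_b,
        config=mcmc,
        priors=priors,
    )
    samples.convergence = convergence_report(samples)
    if not samples.convergence.converged:
        logger.warning(
            "MCMC not converged: max R-hat = %.3f", samples.convergence.max_rhat
        )
    return samples
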