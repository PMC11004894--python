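"""Self-contained Bayesian estimation of a normal yield distribution per group.

Model: dry yields y_i in one treatment group are iid Normal(mu, sigma).  Priors
are weakly informative and data-scaled — mu ~ Normal(ybar, c·s) and
sigma ~ HalfNormal(c·s), with ybar and s the sample mean and sd and c the
``prior_scale_factor`` (default 10).  The posterior p(mu, sigma | y) is
proportional to likelihood x prior; the evidence is never needed because the
sampler only uses posterior ratios.

Sampling is random-walk Metropolis on (mu, log sigma) — the log-sigma
parameterisation adds a +log(sigma) Jacobian term to the target and removes the
sigma > 0 boundary.  Proposal scales start at the asymptotic posterior scales
and, during burn-in only, adapt toward a ~0.3 acceptance rate; post-burn-in
transitions use frozen scales and are therefore exactly posterior-invariant.
Convergence is monitored with split-R̂ (implemented here) and the effective
sample size (via arviz).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """Raised when chains fail the R̂ threshold; carries the diagnostics."""

    def __init__(self, message: str, rhat: dict, ess: dict):
        super().__init__(message)
        self.rhat = rhat
        self.ess = ess


@dataclass(frozen=True)
class ModelSpec:
    """Priors of the per-group normal model (all scales in kg/ha)."""

    mu_loc: float
    mu_scale: float
    sigma_scale: float
    prior_scale_factor: float = 10.0

    def __post_init__(self) -> None:
        if not (self.mu_scale > 0 and self.sigma_scale > 0):
            raise ValueError("prior scales must be positive")

    @classmethod
    def from_data(cls, y, prior_scale_factor: float = 10.0) -> "ModelSpec":
        y = np.asarray(y, dtype=float)
        if y.size < 2:
            raise ValueError("need at least 2 observations to scale the priors")
        s = float(y.std(ddof=1))
        if s == 0.0:
            raise ValueError("zero-variance data: sigma prior scale undefined")
        return cls(mu_loc=float(y.mean()), mu_scale=prior_scale_factor * s,
                   sigma_scale=prior_scale_factor * s,
                   prior_scale_factor=prior_scale_factor)


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 4
    n_iterations: int = 5000
    n_burnin: int = 1000
    proposal_scale_mu: float | None = None        # None: auto from data
    proposal_scale_log_sigma: float | None = None
    adapt: bool = True
    target_acceptance: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be smaller than n_iterations")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")


def log_likelihood(mu, sigma, y):
    """Gaussian iid log-likelihood, via sufficient statistics; vectorised over
    (mu, sigma); -inf wherever sigma <= 0."""
    y = np.asarray(y, dtype=float)
    n, s1, s2 = y.size, float(y.sum()), float((y * y).sum())
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = s2 - 2.0 * mu * s1 + n * mu * mu
        out = -0.5 * n * _LOG2PI - n * np.log(sigma) - sse / (2.0 * sigma ** 2)
    return np.where(sigma > 0, out, -np.inf)


def log_prior(mu, sigma, spec: ModelSpec):
    """Normal prior on mu plus half-normal prior on sigma (log density)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    lp_mu = (-0.5 * _LOG2PI - np.log(spec.mu_scale)
             - 0.5 * ((mu - spec.mu_loc) / spec.mu_scale) ** 2)
    lp_sigma = (0.5 * np.log(2.0 / np.pi) - np.log(spec.sigma_scale)
                - 0.5 * (sigma / spec.sigma_scale) ** 2)
    return np.where(sigma > 0, lp_mu + lp_sigma, -np.inf)


def log_posterior(mu, sigma, y, spec: ModelSpec):
    """Unnormalised log posterior log p(y|mu,sigma) + log p(mu,sigma).

    Finite for every sigma > 0; returns -inf (not an exception) at sigma <= 0
    so a random-walk proposal into the invalid region is simply rejected.
    """
    return log_likelihood(mu, sigma, y) + log_prior(mu, sigma, spec)


@dataclass
class GroupPosterior:
    """Post-burn-in MCMC draws of (mu, sigma) for one treatment group."""

    mu: np.ndarray      # (n_chains, n_draws)
    sigma: np.ndarray   # (n_chains, n_draws)
    acceptance_rate: float
    rhat: dict
    ess: dict
    spec: ModelSpec
    config: SamplerConfig
    n_obs: int

    def __post_init__(self) -> None:
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma draw arrays must share a shape")
        if not (self.sigma > 0).all():
            raise ValueError("all sigma draws must be positive")

    @property
    def n_draws(self) -> int:
        return self.mu.size

    @property
    def mu_flat(self) -> np.ndarray:
        return self.mu.ravel()

    @property
    def sigma_flat(self) -> np.ndarray:
        return self.sigma.ravel()

    def to_dataframe(self) -> pd.DataFrame:
        chains, draws = self.mu.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(chains), draws),
            "iteration": np.tile(np.arange(draws), chains),
            "mu": self.mu_flat,
            "sigma": self.sigma_flat,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GroupPosterior":
        """Rebuild a (diagnostics-free) posterior from serialized draws."""
        chains = df["chain"].nunique()
        mu = df.pivot(index="chain", columns="iteration", values="mu").to_numpy()
        sigma = df.pivot(index="chain", columns="iteration", values="sigma").to_numpy()
        spec = ModelSpec(mu_loc=float(mu.mean()), mu_scale=max(mu.std(), 1.0),
                         sigma_scale=max(sigma.std(), 1.0))
        cfg = SamplerConfig(n_chains=max(chains, 2), n_iterations=mu.shape[1] + 1,
                            n_burnin=0)
        return cls(mu=mu, sigma=sigma, acceptance_rate=np.nan,
                   rhat={"mu": compute_rhat(mu), "sigma": compute_rhat(sigma)},
                   ess={"mu": effective_sample_size(mu),
                        "sigma": effective_sample_size(sigma)},
                   spec=spec, config=cfg, n_obs=0)


def compute_rhat(chains) -> float:
    """Split-chain potential scale reduction factor R̂.

    Each chain is split in half; R̂ compares the between- and within-half-chain
    variances.  The estimator is clamped at 1.0 from below (the raw statistic
    can dip marginally under 1 for finite chains).  Degenerate zero-variance
    chains return 1.0 with a warning.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need a (chains, draws) array with >=2 chains, >=4 draws")
    half = x.shape[1] // 2
    splits = x[:, : 2 * half].reshape(x.shape[0] * 2, half)
    within = float(splits.var(axis=1, ddof=1).mean())
    between = half * float(splits.mean(axis=1).var(ddof=1))
    if within == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined, returning 1.0"
                      if between == 0.0 else
                      "zero within-chain variance with distinct chain means",
                      RuntimeWarning, stacklevel=2)
        return 1.0 if between == 0.0 else np.inf
    var_plus = (half - 1) / half * within + between / half
    return max(float(np.sqrt(var_plus / within)), 1.0)


def effective_sample_size(chains) -> float:
    """Autocorrelation-adjusted effective sample size (arviz ``ess``)."""
    x = np.asarray(chains, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x))


def metropolis_sample(y, spec: ModelSpec | None = None,
                      config: SamplerConfig | None = None,
                      sigma_fixed: float | None = None) -> GroupPosterior:
    """Random-walk Metropolis sampling of the per-group posterior.

    Parameters
    ----------
    y : 1-d array of dry yields (kg/ha).
    spec : priors; defaults to :meth:`ModelSpec.from_data`.
    config : chain/iteration counts, proposal scales, adaptation, seed.
    sigma_fixed : if given, sigma is held at this value and only mu is
        sampled — the known-variance case with a conjugate closed form,
        used as an independent oracle for the sampler.

    All chains run under one seeded generator; identical inputs give
    bit-identical chains.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty data")
    spec = spec if spec is not None else ModelSpec.from_data(y)
    config = config if config is not None else SamplerConfig()

    n = y.size
    s = float(y.std(ddof=1)) if n > 1 else float(spec.sigma_scale)
    s = s if s > 0 else float(spec.sigma_scale)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    C, T, B = config.n_chains, config.n_iterations, config.n_burnin

    # asymptotic posterior scales: sd(mu)≈s/√n, sd(log sigma)≈1/√(2n)
    step_mu = config.proposal_scale_mu
    step_ls = config.proposal_scale_log_sigma
    if step_mu is None:
        step_mu = 2.4 * s / np.sqrt(n)
    if step_ls is None:
        step_ls = 2.4 / np.sqrt(2.0 * n)
    scale = np.ones(C)  # per-chain adaptive multiplier

    mu = spec.mu_loc + (s / np.sqrt(n)) * rng.standard_normal(C)
    if sigma_fixed is not None:
        if sigma_fixed <= 0:
            raise ValueError("sigma_fixed must be positive")
        ls = np.full(C, np.log(sigma_fixed))
    else:
        ls = np.log(s) + 0.1 * rng.standard_normal(C)

    def target(mu_v, ls_v):
        # +ls Jacobian for the log-sigma parameterisation (absent when fixed)
        lp = log_posterior(mu_v, np.exp(ls_v), y, spec)
        return lp if sigma_fixed is not None else lp + ls_v

    lp = target(mu, ls)
    keep = T - B
    mu_out = np.empty((C, keep))
    sg_out = np.empty((C, keep))
    accepted_post = 0
    window_acc = np.zeros(C)
    window_len = 50

    for it in range(T):
        prop_mu = mu + scale * step_mu * rng.standard_normal(C)
        if sigma_fixed is None:
            prop_ls = ls + scale * step_ls * rng.standard_normal(C)
        else:
            prop_ls = ls
        lp_prop = target(prop_mu, prop_ls)
        accept = np.log(rng.random(C)) < lp_prop - lp
        mu = np.where(accept, prop_mu, mu)
        ls = np.where(accept, prop_ls, ls)
        lp = np.where(accept, lp_prop, lp)
        if it < B:
            if config.adapt:
                window_acc += accept
                if (it + 1) % window_len == 0:
                    rate = window_acc / window_len
                    scale *= np.exp(rate - config.target_acceptance)
                    scale = np.clip(scale, 1e-3, 1e3)
                    window_acc[:] = 0.0
        else:
            accepted_post += int(accept.sum())
            mu_out[:, it - B] = mu
            sg_out[:, it - B] = np.exp(ls)

    acceptance = accepted_post / (C * keep)
    if acceptance < 0.05:
        warnings.warn(f"low post-burn-in acceptance rate {acceptance:.3f}; "
                      "chains may be poorly mixed", RuntimeWarning, stacklevel=2)

    rhat = {"mu": compute_rhat(mu_out)}
    ess = {"mu": effective_sample_size(mu_out)}
    if sigma_fixed is None:
        rhat["sigma"] = compute_rhat(sg_out)
        ess["sigma"] = effective_sample_size(sg_out)
    else:
        rhat["sigma"] = 1.0
        ess["sigma"] = float(C * keep)
    logger.info("metropolis: acceptance %.3f, rhat mu=%.4f sigma=%.4f",
                acceptance, rhat["mu"], rhat["sigma"])
    return GroupPosterior(mu=mu_out, sigma=sg_out, acceptance_rate=acceptance,
                          rhat=rhat, ess=ess, spec=spec, config=config, n_obs=n)


def fit_group(y, prior_scale_factor: float = 10.0,
              config: SamplerConfig | None = None,
              rhat_threshold: float = 1.01,
              sigma_fixed: float | None = None) -> GroupPosterior:
    """Fit the normal model to one group's yields and vet convergence.

    Builds the data-scaled priors, runs :func:`metropolis_sample`, and raises
    :class:`ConvergenceError` (carrying R̂ and ESS) if any parameter's split-R̂
    exceeds ``rhat_threshold``.
    """
    y = np.asarray(y, dtype=float)
    spec = ModelSpec.from_data(y, prior_scale_factor=prior_scale_factor)
    post = metropolis_sample(y, spec=spec, config=config, sigma_fixed=sigma_fixed)
    worst = max(post.rhat.values())
    if worst > rhat_threshold:
        raise ConvergenceError(
            f"split R-hat {worst:.4f} exceeds threshold {rhat_threshold}",
            rhat=post.rhat, ess=post.ess)
    return post
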