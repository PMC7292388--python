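"""Bayesian estimation of behavior-frequency and concentration distributions.

Two small models, each fit per pathway x population x neighborhood:

* **Frequency**: monthly contact counts f_i ~ NegativeBinomial(r, p) with
  mean m = r(1-p)/p.  Priors r ~ Gamma(shape, rate), p ~ Beta(a, b).  The
  sampler is Metropolis-within-Gibbs: p has a conjugate Beta full
  conditional given r (the NB likelihood is p^{nr} (1-p)^{S} in p), and r
  is updated by an adaptive random-walk Metropolis step on log r.

* **Concentration**: observed log10 concentrations y_i ~ Normal(mu, sigma^2);
  left-censored samples contribute Phi((L - mu)/sigma) and right-censored
  samples 1 - Phi((U - mu)/sigma) to the likelihood, so non-detects and
  saturated plates inform the fit without substitution.  Priors
  mu ~ Normal(m0, s0^2), sigma ~ Half-Normal(scale); both parameters move by
  adaptive random-walk Metropolis (mu directly, sigma on the log scale).

Proposal scales adapt toward a ~40% acceptance rate during burn-in only, so
a seeded run is bit-reproducible.  Multiple chains are run from dispersed
starts; split-chain R-hat and effective sample size are computed with arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_ndtr

from .config import McmcSettings, PriorSpec
from .microbiology import (ConcentrationEstimate, LEFT_CENSORED, OBSERVED,
                           RIGHT_CENSORED)

_ADAPT_TARGET = 0.40


class EstimationError(ValueError):
    """Raised when data cannot support the requested fit."""


def _rhat(draws: np.ndarray) -> float:
    """Split-chain R-hat of a (chains, draws) array via arviz."""
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(az.convert_to_dataset(draws))["x"].values)


def _ess(draws: np.ndarray) -> float:
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(az.convert_to_dataset(draws))["x"].values)


@dataclass
class FrequencyPosterior:
    """Posterior draws of the negative-binomial frequency parameters."""

    pathway: str
    population: str
    neighborhood: str
    r: np.ndarray  # (chains, draws)
    p: np.ndarray
    n_obs: int
    accept_rate_r: float
    warnings: tuple[str, ...] = ()

    @property
    def mean_contacts(self) -> np.ndarray:
        """Draws of the NB mean m = r(1-p)/p, flattened across chains."""
        return (self.r * (1 - self.p) / self.p).ravel()

    @property
    def draws(self) -> np.ndarray:
        """Flattened (n, 2) array of (r, p) draws."""
        return np.column_stack([self.r.ravel(), self.p.ravel()])

    def rhat(self) -> float:
        return _rhat(self.r * (1 - self.p) / self.p)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r": self.r.ravel(), "p": self.p.ravel(),
            "mean_contacts": self.mean_contacts,
        })


@dataclass
class ConcentrationPosterior:
    """Posterior draws of the log10-concentration normal parameters."""

    pathway: str
    neighborhood: str
    mu: np.ndarray  # (chains, draws)
    sigma: np.ndarray
    n_obs: int
    n_censored: int
    accept_rate_mu: float
    accept_rate_sigma: float
    warnings: tuple[str, ...] = ()

    @property
    def draws(self) -> np.ndarray:
        return np.column_stack([self.mu.ravel(), self.sigma.ravel()])

    def rhat(self) -> float:
        return _rhat(self.mu)

    def ess_mu(self) -> float:
        return _ess(self.mu)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.mu.ravel(), "sigma": self.sigma.ravel()})


# ----------------------------------------------------------------------------
# Negative-binomial frequency model


def _nb_loglik_r(r: float, counts: np.ndarray, log_p: float) -> float:
    # terms of the NB log-likelihood that depend on r, at fixed p
    n = counts.size
    return float(np.sum(gammaln(counts + r)) - n * gammaln(r) + n * r * log_p)


def fit_frequency(counts: list[float] | np.ndarray,
                  prior: PriorSpec,
                  settings: McmcSettings,
                  pathway: str = "",
                  population: str = "",
                  neighborhood: str = "",
                  min_obs: int = 5) -> FrequencyPosterior:
    """Fit the negative-binomial monthly-contact model.

    Category-midpoint counts are non-integer; they are rounded half-up to
    the nearest integer for the NB likelihood (half-up so that the 0.5
    midpoint of a "less than monthly" answer — which asserts nonzero
    contact — does not collapse to zero).  An all-zero count vector is
    legal (nobody reports the behavior): the posterior mean contact rate
    concentrates near zero and a warning is attached rather than failing.
    """
    y = np.floor(np.asarray(counts, dtype=float) + 0.5).astype(np.int64)
    if y.size < min_obs:
        raise EstimationError(
            f"need at least {min_obs} observations to fit frequencies, "
            f"got {y.size}")
    if np.any(y < 0):
        raise EstimationError("negative monthly counts are invalid")
    warns: list[str] = []
    if np.all(y == 0):
        warns.append("all respondents report zero contacts; frequency "
                     "posterior is prior-dominated near zero")

    n = y.size
    S = int(y.sum())
    nchains, ndraws = settings.chains, settings.draws_per_chain
    r_out = np.empty((nchains, ndraws))
    p_out = np.empty((nchains, ndraws))
    n_acc = 0
    n_prop = 0

    for chain in range(nchains):
        rng = np.random.default_rng(
            np.random.SeedSequence(settings.seed, spawn_key=(0, chain)))
        # dispersed starts around a method-of-moments guess
        m0 = max(y.mean(), 0.1)
        v0 = max(y.var(), m0 + 0.1)
        r = max((m0 * m0) / max(v0 - m0, 0.1), 0.1) * np.exp(rng.normal(0, 0.5))
        scale = settings.prop_scale_logr
        kept = 0
        for it in range(settings.iterations):
            in_burn = it < settings.burn_in
            # Gibbs: p | r, y ~ Beta(a + n r, b + S)
            p = rng.beta(prior.p_a + n * r, prior.p_b + S)
            p = min(max(p, 1e-12), 1 - 1e-12)
            # Metropolis on log r
            log_p = np.log(p)
            prop = r * np.exp(rng.normal(0.0, scale))
            cur = _nb_loglik_r(r, y, log_p) \
                + prior.r_shape * np.log(r) - prior.r_rate * r
            new = _nb_loglik_r(prop, y, log_p) \
                + prior.r_shape * np.log(prop) - prior.r_rate * prop
            # includes the log-r Jacobian via the extra log terms above
            accept = np.log(rng.uniform()) < new - cur
            if accept:
                r = prop
            if not in_burn:
                n_prop += 1
                n_acc += int(accept)
                if (it - settings.burn_in) % settings.thin == 0 and kept < ndraws:
                    r_out[chain, kept] = r
                    p_out[chain, kept] = p
                    kept += 1
            # simple Robbins-Monro style adaptation, burn-in only
            if in_burn:
                scale *= np.exp((1.0 if accept else 0.0) - _ADAPT_TARGET) ** 0.05
                scale = min(max(scale, 1e-3), 10.0)

    return FrequencyPosterior(
        pathway=pathway, population=population, neighborhood=neighborhood,
        r=r_out, p=p_out, n_obs=n,
        accept_rate_r=n_acc / max(n_prop, 1),
        warnings=tuple(warns))


# ----------------------------------------------------------------------------
# Log-normal concentration model with censoring


_LOG_2PI = np.log(2 * np.pi)


def _conc_loglik(mu: float, sigma: float, obs: np.ndarray,
                 left: np.ndarray, right: np.ndarray) -> float:
    ll = 0.0
    if obs.size:
        z = (obs - mu) / sigma
        ll += -0.5 * float(z @ z) - obs.size * (np.log(sigma)
                                                + 0.5 * _LOG_2PI)
    if left.size:  # P(X <= L)
        ll += float(np.sum(log_ndtr((left - mu) / sigma)))
    if right.size:  # P(X > U)
        ll += float(np.sum(log_ndtr((mu - right) / sigma)))
    return ll


def fit_concentration(estimates: list[ConcentrationEstimate],
                      prior: PriorSpec,
                      settings: McmcSettings,
                      pathway: str = "",
                      neighborhood: str = "") -> ConcentrationPosterior:
    """Fit the normal model of log10 concentrations with censored likelihood.

    Requires at least three samples of which at least one is fully observed;
    a pathway where every plate was a non-detect (or saturated) carries no
    location information beyond its limits and is refused.
    """
    obs = np.array([e.log10_concentration for e in estimates
                    if e.censoring == OBSERVED])
    left = np.array([e.log10_concentration for e in estimates
                     if e.censoring == LEFT_CENSORED])
    right = np.array([e.log10_concentration for e in estimates
                      if e.censoring == RIGHT_CENSORED])
    n_total = obs.size + left.size + right.size
    if n_total < 3 or obs.size == 0:
        raise EstimationError(
            "cannot estimate concentration distribution: need >=3 samples "
            f"with >=1 observed (got {n_total} total, {obs.size} observed)")

    warns: list[str] = []
    if obs.size >= 2 and np.ptp(obs) == 0:
        warns.append("all observed log10 concentrations identical; sigma "
                     "is prior-dominated")

    nchains, ndraws = settings.chains, settings.draws_per_chain
    mu_out = np.empty((nchains, ndraws))
    sg_out = np.empty((nchains, ndraws))
    acc_mu = acc_sg = prop_ct = 0

    center = float(obs.mean())
    spread = float(obs.std()) if obs.size > 1 and obs.std() > 0 else 1.0

    for chain in range(nchains):
        rng = np.random.default_rng(
            np.random.SeedSequence(settings.seed, spawn_key=(1, chain)))
        mu = center + rng.normal(0, spread)
        sigma = spread * np.exp(rng.normal(0, 0.3))
        s_mu = settings.prop_scale_mu * spread
        s_ls = settings.prop_scale_logsigma
        ll = _conc_loglik(mu, sigma, obs, left, right)
        kept = 0
        for it in range(settings.iterations):
            in_burn = it < settings.burn_in
            # mu update
            mu_p = mu + rng.normal(0.0, s_mu)
            ll_p = _conc_loglik(mu_p, sigma, obs, left, right)
            dprior = ((mu - prior.mu_loc) ** 2 - (mu_p - prior.mu_loc) ** 2) \
                / (2 * prior.mu_scale ** 2)
            a_mu = np.log(rng.uniform()) < ll_p - ll + dprior
            if a_mu:
                mu, ll = mu_p, ll_p
            # sigma update on log scale; half-normal prior + Jacobian
            sg_p = sigma * np.exp(rng.normal(0.0, s_ls))
            ll_p = _conc_loglik(mu, sg_p, obs, left, right)
            dprior = (-sg_p ** 2 / (2 * prior.sigma_scale ** 2)
                      + sigma ** 2 / (2 * prior.sigma_scale ** 2)
                      + np.log(sg_p) - np.log(sigma))
            a_sg = np.log(rng.uniform()) < ll_p - ll + dprior
            if a_sg:
                sigma, ll = sg_p, ll_p
            if in_burn:
                s_mu *= np.exp((1.0 if a_mu else 0.0) - _ADAPT_TARGET) ** 0.05
                s_ls *= np.exp((1.0 if a_sg else 0.0) - _ADAPT_TARGET) ** 0.05
            else:
                prop_ct += 1
                acc_mu += int(a_mu)
                acc_sg += int(a_sg)
                if (it - settings.burn_in) % settings.thin == 0 and kept < ndraws:
                    mu_out[chain, kept] = mu
                    sg_out[chain, kept] = sigma
                    kept += 1

    return ConcentrationPosterior(
        pathway=pathway, neighborhood=neighborhood,
        mu=mu_out, sigma=sg_out,
        n_obs=n_total, n_censored=int(left.size + right.size),
        accept_rate_mu=acc_mu / max(prop_ct, 1),
        accept_rate_sigma=acc_sg / max(prop_ct, 1),
        warnings=tuple(warns))


# ----------------------------------------------------------------------------


def posterior_summary(posterior: FrequencyPosterior | ConcentrationPosterior
                      ) -> pd.DataFrame:
    """Mean, sd, and 2.5/50/97.5 percentiles per parameter.

    Percentiles use linear interpolation between order statistics
    (numpy's default, Hyndman-Fan type 7).
    """
    frame = posterior.frame()
    if frame.empty:
        raise EstimationError("posterior has no draws to summarize")
    rows = []
    for col in frame.columns:
        v = frame[col].to_numpy()
        q = np.percentile(v, [2.5, 50, 97.5])
        rows.append({"parameter": col, "mean": v.mean(), "sd": v.std(ddof=1),
                     "q2.5": q[0], "median": q[1], "q97.5": q[2]})
    return pd.DataFrame(rows)
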