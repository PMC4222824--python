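"""Metropolis-Hastings inversion of the maximum carboxylation rate against a
site's observed daily GPP, posterior-mode point estimates, and per-PFT
pooling of site-level optima.

The target density is a uniform prior on [prior_lo, prior_hi] times an iid
Gaussian likelihood of observed daily GPP given the forward canopy model.
The point estimate is the most-frequent value of the post-burn-in chain,
binned at ``mode_bin_width`` (1e-6 mol m-2 s-1, i.e. the 1-umol precision
of the PFT parameter table).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .photosynthesis import PhotoParams, forward_gpp
from .site_io import SiteSeries, daily_values

log = logging.getLogger("gppval")

__all__ = [
    "McmcConfig", "McmcChain", "make_log_posterior", "log_posterior",
    "metropolis_hastings", "mh_sample", "posterior_mode", "pool_by_pft",
    "AnovaResult",
]


@dataclass(frozen=True)
class McmcConfig:
    n_samples: int = 10000
    burn_in: int = 1000                 # excluded from mode estimation
    proposal_sd: float | None = None    # None -> 5% of the prior range
    prior_lo: float = 1e-6              # mol CO2 m-2 s-1
    prior_hi: float = 300e-6
    likelihood_sd: float = 1.0          # g C m-2 day-1
    seed: int = 0
    mode_bin_width: float = 1e-6
    tune: bool = True                   # proposal-sd tuning during burn-in only

    def __post_init__(self):
        if not self.prior_lo < self.prior_hi:
            raise ValueError("need prior_lo < prior_hi")
        if not self.n_samples > self.burn_in:
            raise ValueError("need n_samples > burn_in")
        if self.proposal_sd is not None and not self.proposal_sd > 0:
            raise ValueError("proposal_sd must be > 0")
        if not self.likelihood_sd > 0:
            raise ValueError("likelihood_sd must be > 0")
        if not self.mode_bin_width > 0:
            raise ValueError("mode_bin_width must be > 0")

    @property
    def proposal_sd_effective(self) -> float:
        return (self.proposal_sd if self.proposal_sd is not None
                else 0.05 * (self.prior_hi - self.prior_lo))


@dataclass
class McmcChain:
    samples: np.ndarray
    log_posts: np.ndarray
    acceptance_rate: float
    mode: float
    config: McmcConfig

    def __len__(self) -> int:
        return len(self.samples)


def make_log_posterior(series: SiteSeries, params: PhotoParams,
                       config: McmcConfig, pathway: str = "C3"):
    """Build a fast closure v -> unnormalized log posterior.

    Per-day LAI and the observation vector are precomputed once; each call
    runs the vectorized forward model at the candidate value.
    """
    obs = series.data["gpp_obs"].to_numpy(dtype=float)
    ok = np.isfinite(obs)
    if not ok.any():
        raise ValueError("series has no observed GPP days")
    lai_daily = daily_values(series, "lai")
    obs_ok = obs[ok]
    sd = config.likelihood_sd
    norm = -0.5 * len(obs_ok) * math.log(2.0 * math.pi * sd * sd)

    def logpost(vcmax: float) -> float:
        if not (config.prior_lo <= vcmax <= config.prior_hi) or not np.isfinite(vcmax):
            return -np.inf
        sim = forward_gpp(series, params, pathway, vcmax=vcmax, lai_daily=lai_daily)
        resid = obs_ok - sim[ok]
        return norm - 0.5 * float(resid @ resid) / (sd * sd)

    return logpost


def log_posterior(vcmax: float, series: SiteSeries, params: PhotoParams,
                  config: McmcConfig, pathway: str = "C3") -> float:
    """Unnormalized log posterior of one candidate value (convenience
    wrapper; use :func:`make_log_posterior` for repeated evaluation)."""
    return make_log_posterior(series, params, config, pathway)(vcmax)


def metropolis_hastings(logpost, config: McmcConfig,
                        start: float | None = None):
    """Random-walk Metropolis-Hastings on a 1-D target.

    Returns (samples, log_posts, acceptance_rate). The Gaussian proposal sd
    is optionally rescaled toward 20-50% acceptance during burn-in only, so
    the post-burn-in kernel is fixed and valid.
    """
    rng = np.random.default_rng(config.seed)
    sd = config.proposal_sd_effective
    x = start if start is not None else 0.5 * (config.prior_lo + config.prior_hi)
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("start point has zero posterior density")
    samples = np.empty(config.n_samples)
    lps = np.empty(config.n_samples)
    n_accept = 0
    window_accept = 0
    for i in range(config.n_samples):
        prop = x + sd * rng.standard_normal()
        lp_prop = logpost(prop)
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            n_accept += 1
            window_accept += 1
        samples[i] = x
        lps[i] = lp
        if config.tune and i < config.burn_in and (i + 1) % 100 == 0:
            rate = window_accept / 100.0
            if rate < 0.2:
                sd *= 0.7
            elif rate > 0.5:
                sd *= 1.4
            window_accept = 0
    acceptance = n_accept / config.n_samples
    if acceptance < 0.01:
        log.warning("MCMC acceptance rate %.4f < 0.01; chain may be poorly mixed",
                    acceptance)
    return samples, lps, acceptance


def posterior_mode(chain: "McmcChain | tuple", config: McmcConfig | None = None) -> float:
    """Highest-frequency value of the post-burn-in chain: center of the most
    populated histogram bin of width ``mode_bin_width`` spanning the prior.
    Count ties break toward the bin with the higher mean log posterior."""
    if isinstance(chain, McmcChain):
        samples, lps, config = chain.samples, chain.log_posts, chain.config
    else:
        samples, lps = chain
        if config is None:
            raise ValueError("config required when passing raw samples")
    if len(samples) <= config.burn_in:
        raise ValueError("chain not longer than burn-in")
    s = samples[config.burn_in:]
    lp = lps[config.burn_in:]
    w = config.mode_bin_width
    # bins centered on prior_lo + k*w, so a chain sitting exactly on a
    # multiple of the bin width reports that value
    n_bins = int(round((config.prior_hi - config.prior_lo) / w)) + 1
    idx = np.clip(np.rint((s - config.prior_lo) / w).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    tied = np.flatnonzero(counts == counts.max())
    if len(tied) > 1:
        mean_lp = np.array([lp[idx == b].mean() for b in tied])
        bin_i = int(tied[int(np.argmax(mean_lp))])
    else:
        bin_i = int(tied[0])
    return float(config.prior_lo + bin_i * w)


def mh_sample(series: SiteSeries, params: PhotoParams, config: McmcConfig,
              pathway: str = "C3") -> McmcChain:
    """Run the full inversion for one site and return the chain with its
    posterior-mode summary."""
    logpost = make_log_posterior(series, params, config, pathway)
    samples, lps, acc = metropolis_hastings(logpost, config)
    chain = McmcChain(samples=samples, log_posts=lps, acceptance_rate=acc,
                      mode=0.0, config=config)
    chain.mode = posterior_mode(chain)
    log.info("%s: inversion mode=%.3g mol m-2 s-1, acceptance=%.3f",
             series.site_id, chain.mode, acc)
    return chain


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float


def pool_by_pft(site_optima) -> tuple[pd.DataFrame, AnovaResult | None]:
    """Pool site-level optima into per-PFT means (the "per-type" parameter
    scheme) and run a one-way ANOVA across PFTs.

    ``site_optima``: iterable of (site_id, pft, vcmax_opt). The ANOVA is
    omitted (None, with a log notice) when fewer than two groups have at
    least two members each.
    """
    frame = pd.DataFrame(site_optima, columns=["site_id", "pft", "vcmax_opt"])
    if frame.empty:
        raise ValueError("no site optima to pool")
    table = (frame.groupby("pft")["vcmax_opt"]
             .agg(mean_vcmax="mean", n_sites="count").reset_index())
    groups = [g.to_numpy(dtype=float) for _, g in frame.groupby("pft")["vcmax_opt"]
              if len(g) >= 2]
    if len(groups) < 2:
        log.warning("ANOVA omitted: need >= 2 PFTs with >= 2 sites each")
        return table, None
    if np.ptp(np.concatenate(groups)) == 0:   # f_oneway would yield 0/0
        return table, AnovaResult(0.0, 1.0)
    f_stat, p = stats.f_oneway(*groups)
    return table, AnovaResult(float(f_stat), float(p))
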