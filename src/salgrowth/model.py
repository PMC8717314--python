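"""Hierarchical von Bertalanffy growth-increment model (Wang/Fabens form).

The observation unit is a recapture pair: start length X, increment Z over
T days. The mean increment is

    E[Z] = (l_inf + beta * (X - x_bar) - X) * (1 - exp(-k * T))

where ``l_inf + beta * (X - x_bar)`` is a first-order approximation to the
individual's asymptotic length (heterogeneous asymptotes enter through the
slope ``beta`` on the centred start length) and ``k`` is the growth
coefficient. Harvest acts multiplicatively on k through a log-linear
submodel with site and year random intercepts truncated to [-2, 2]
(roughly a sevenfold swing around the mean rate):

    log(k_i) = alpha0 + alpha_treat * harvest_i + eta_site[i] + eta_year[i]

Residuals are Gaussian with constant SD ``sigma_resid`` (model plus
measurement error). Intervals straddling a site's harvest date have an
unknown harvest state, marginalized over a Bernoulli(0.5) prior; intervals
spanning several calendar years mix the year effect with equal weight over
the years spanned. Both discrete latents are marginalized analytically by
default, which leaves a small Gaussian mixture per interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf, logsumexp
from scipy.stats import norm

from .io_cmr import HARVEST_MISSING, GrowthInterval, ModelData

__all__ = [
    "GrowthParameters",
    "PriorConfig",
    "PackedData",
    "expected_increment",
    "growth_coefficient",
    "interval_loglikelihood",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "zero_increment_length",
    "mean_growth_curve",
    "pack_model_data",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GrowthParameters:
    """One state of the growth model.

    ``eta_site`` / ``eta_year`` are arrays aligned with ``ModelData``'s
    ``site_index`` / ``year_index``; each element lies in [-2, 2].
    """

    l_inf: float
    beta: float
    alpha0: float
    alpha_treat: float
    eta_site: np.ndarray
    eta_year: np.ndarray
    sigma_site: float
    sigma_year: float
    sigma_resid: float

    def __post_init__(self) -> None:
        self.eta_site = np.atleast_1d(np.asarray(self.eta_site, dtype=float))
        self.eta_year = np.atleast_1d(np.asarray(self.eta_year, dtype=float))


@dataclass(frozen=True)
class PriorConfig:
    """Prior specification; defaults are deliberately vague.

    The uniform(0, 0.1) prior is placed on the baseline growth coefficient
    ``exp(alpha0)`` (per-day scale) and induces the prior on ``alpha0`` by
    change of variables. All standard deviations get exponential(1) priors.
    Random intercepts are Gaussian truncated to ±``re_truncation`` with
    renormalized density.
    """

    k_baseline_bounds: tuple[float, float] = (0.0, 0.1)
    alpha_treat_sd: float = 10.0
    beta_sd: float = 1.0
    l_inf_bounds: tuple[float, float] = (0.0, 100.0)
    sd_prior_rate: float = 1.0
    missing_harvest_prob: float = 0.5
    re_truncation: float = 2.0


def expected_increment(x, t, k, l_inf, beta, x_bar):
    """Mean length increment (mm) over t days from start length x.

    Negative when x exceeds the individual's approximate asymptote.
    Vectorized over any broadcastable combination of arguments.
    """
    x = np.asarray(x, dtype=float)
    return (l_inf + beta * (x - x_bar) - x) * -np.expm1(-np.asarray(k) * np.asarray(t))


def growth_coefficient(alpha0, alpha_treat, harvest, eta_site_i=0.0, eta_year_i=0.0):
    """Per-day growth coefficient k from the log-linear submodel."""
    return np.exp(alpha0 + alpha_treat * np.asarray(harvest) + eta_site_i + eta_year_i)


def zero_increment_length(l_inf: float, beta: float, x_bar: float) -> float:
    """Start length at which the expected increment is zero.

    Solves l_inf + beta*(X - x_bar) - X = 0; diverges as beta -> 1 (every
    animal would grow forever).
    """
    if beta == 1.0:
        raise ValueError("beta = 1 leaves no finite zero-growth length")
    return (l_inf - beta * x_bar) / (1.0 - beta)


def mean_growth_curve(params: GrowthParameters, harvest: int, age_grid) -> np.ndarray:
    """Population-mean length-at-age curve L(a) = l_inf * (1 - e^(-k a)).

    Random effects sit at zero and the beta term at its population mean, so
    k = exp(alpha0 + alpha_treat * harvest). ``age_grid`` is in days.
    """
    a = np.asarray(age_grid, dtype=float)
    k = growth_coefficient(params.alpha0, params.alpha_treat, harvest)
    return params.l_inf * -np.expm1(-k * a)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


@dataclass
class PackedData:
    """ModelData flattened into component arrays for fast likelihood evals.

    Each interval contributes one mixture component per (year spanned) x
    (harvest state if missing); components for an interval are contiguous,
    delimited by ``offsets`` for segment reductions.
    """

    x: np.ndarray
    z: np.ndarray
    t: np.ndarray
    x_bar: float
    n_sites: int
    n_years: int
    comp_interval: np.ndarray  # interval index per component
    comp_site: np.ndarray
    comp_year: np.ndarray
    comp_harvest: np.ndarray
    comp_logw: np.ndarray
    offsets: np.ndarray  # start index of each interval's components
    site_names: list = field(default_factory=list)
    year_names: list = field(default_factory=list)

    @property
    def n_intervals(self) -> int:
        return self.x.size


def pack_model_data(data: ModelData) -> PackedData:
    x, z, t = [], [], []
    ci, cs, cy, ch, cw, offsets = [], [], [], [], [], []
    for i, iv in enumerate(data.intervals):
        x.append(iv.x_svl_mm)
        z.append(iv.z_mm)
        t.append(iv.t_days)
        offsets.append(len(ci))
        harvests = (0, 1) if iv.harvest_state == HARVEST_MISSING else (iv.harvest_state,)
        logw = -np.log(len(harvests) * len(iv.years_spanned))
        for h in harvests:
            for y in iv.years_spanned:
                ci.append(i)
                cs.append(data.site_index[iv.site_id])
                cy.append(data.year_index[y])
                ch.append(h)
                cw.append(logw)
    return PackedData(
        x=np.array(x),
        z=np.array(z),
        t=np.array(t, dtype=float),
        x_bar=data.x_bar_mm,
        n_sites=data.n_sites,
        n_years=data.n_years,
        comp_interval=np.array(ci, dtype=np.intp),
        comp_site=np.array(cs, dtype=np.intp),
        comp_year=np.array(cy, dtype=np.intp),
        comp_harvest=np.array(ch, dtype=float),
        comp_logw=np.array(cw),
        offsets=np.array(offsets, dtype=np.intp),
        site_names=sorted(data.site_index, key=data.site_index.get),
        year_names=sorted(data.year_index, key=data.year_index.get),
    )


def _component_logpdf(packed: PackedData, p: GrowthParameters) -> np.ndarray:
    """Gaussian log-density of each mixture component (without its weight)."""
    log_k = (
        p.alpha0
        + p.alpha_treat * packed.comp_harvest
        + p.eta_site[packed.comp_site]
        + p.eta_year[packed.comp_year]
    )
    idx = packed.comp_interval
    mu = expected_increment(
        packed.x[idx], packed.t[idx], np.exp(log_k), p.l_inf, p.beta, packed.x_bar
    )
    resid = (packed.z[idx] - mu) / p.sigma_resid
    return -0.5 * resid * resid - np.log(p.sigma_resid) - 0.5 * _LOG_2PI


def _segment_logsumexp(values: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """logsumexp over contiguous segments delimited by offsets."""
    vmax = np.maximum.reduceat(values, offsets)
    shifted = np.exp(values - np.repeat(vmax, np.diff(np.append(offsets, values.size))))
    return vmax + np.log(np.add.reduceat(shifted, offsets))


def log_likelihood(packed: PackedData, p: GrowthParameters) -> float:
    """Marginal log-likelihood: discrete latents summed out per interval."""
    if p.sigma_resid <= 0:
        raise ValueError("sigma_resid must be positive")
    comp = packed.comp_logw + _component_logpdf(packed, p)
    return float(np.sum(_segment_logsumexp(comp, packed.offsets)))


def interval_loglikelihood(
    interval: GrowthInterval, params: GrowthParameters, x_bar: float,
    site_index: dict | None = None, year_index: dict | None = None,
) -> float:
    """Log-density of one interval's increment under the mixture likelihood.

    Marginalizes the harvest state (equal-weight two-component mixture when
    missing) and the year effect (equal weight over years spanned). With an
    observed harvest state and a single year this is one Gaussian density.
    ``site_index``/``year_index`` default to a single-site / years-as-listed
    indexing for standalone use.
    """
    if params.sigma_resid <= 0:
        raise ValueError("sigma_resid must be positive")
    site_index = site_index if site_index is not None else {interval.site_id: 0}
    year_index = (
        year_index
        if year_index is not None
        else {y: i for i, y in enumerate(interval.years_spanned)}
    )
    harvests = (
        (0, 1) if interval.harvest_state == HARVEST_MISSING else (interval.harvest_state,)
    )
    terms = []
    logw = -np.log(len(harvests) * len(interval.years_spanned))
    for h in harvests:
        for y in interval.years_spanned:
            k = growth_coefficient(
                params.alpha0,
                params.alpha_treat,
                h,
                params.eta_site[site_index[interval.site_id]],
                params.eta_year[year_index[y]],
            )
            mu = expected_increment(
                interval.x_svl_mm, interval.t_days, k, params.l_inf, params.beta, x_bar
            )
            terms.append(logw + norm.logpdf(interval.z_mm, mu, params.sigma_resid))
    return float(logsumexp(terms))


# ---------------------------------------------------------------------------
# Priors and posterior
# ---------------------------------------------------------------------------


def _truncnorm_logpdf(eta: np.ndarray, sigma: float, bound: float) -> float:
    """Log-density of Gaussian(0, sigma) truncated to [-bound, bound]."""
    if np.any(np.abs(eta) > bound):
        return -np.inf
    # renormalization: P(|N(0,sigma)| <= bound) = erf(bound / (sigma*sqrt(2)))
    log_norm = np.log(erf(bound / (sigma * np.sqrt(2.0))))
    return float(
        np.sum(-0.5 * (eta / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG_2PI - log_norm)
    )


def log_prior(p: GrowthParameters, priors: PriorConfig = PriorConfig()) -> float:
    """Joint log-prior; -inf outside support rather than raising."""
    lo_l, hi_l = priors.l_inf_bounds
    if not (lo_l < p.l_inf < hi_l):
        return -np.inf
    lo_k, hi_k = priors.k_baseline_bounds
    k0 = np.exp(p.alpha0)
    if not (lo_k < k0 < hi_k):
        return -np.inf
    if p.sigma_site <= 0 or p.sigma_year <= 0 or p.sigma_resid <= 0:
        return -np.inf
    lp = -np.log(hi_l - lo_l)
    # uniform on k0, expressed on alpha0 = log k0: density k0 / (hi - lo)
    lp += p.alpha0 - np.log(hi_k - lo_k)
    lp += norm.logpdf(p.alpha_treat, 0.0, priors.alpha_treat_sd)
    lp += norm.logpdf(p.beta, 0.0, priors.beta_sd)
    rate = priors.sd_prior_rate
    for s in (p.sigma_site, p.sigma_year, p.sigma_resid):
        lp += np.log(rate) - rate * s
    lp += _truncnorm_logpdf(p.eta_site, p.sigma_site, priors.re_truncation)
    lp += _truncnorm_logpdf(p.eta_year, p.sigma_year, priors.re_truncation)
    return float(lp)


def log_posterior(
    data: ModelData | PackedData,
    p: GrowthParameters,
    priors: PriorConfig = PriorConfig(),
) -> float:
    """Unnormalized log-posterior; -inf outside prior support."""
    packed = data if isinstance(data, PackedData) else pack_model_data(data)
    lp = log_prior(p, priors)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(packed, p)
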