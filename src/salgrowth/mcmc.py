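"""MCMC machinery for the growth model.

Sampling uses an adaptive random-walk Metropolis chain (global Gaussian
proposal; Haario-style covariance adaptation and Robbins–Monro step-size
tuning during burn-in, frozen afterwards so the retained chain is
Markovian). Standard deviations are sampled on the log scale with the
Jacobian folded into the target. Discrete latents (missing harvest state,
multi-year year assignment) are marginalized analytically by default;
``mode='latent'`` instead carries them explicitly and Gibbs-resamples them
each iteration, reproducing the formulation a BUGS/JAGS implementation
would use. Both target the same posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .io_cmr import ModelData
from .model import (
    GrowthParameters,
    PackedData,
    PriorConfig,
    pack_model_data,
)

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "PosteriorSummary",
    "sample_posterior",
    "gelman_rubin",
    "potential_scale_reduction",
    "summarize_posterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings. Defaults are desk-scale; ``paper_scale()`` returns
    the long-run configuration (5 chains of 1e6, burn-in 2e5, thin 50)."""

    n_chains: int = 4
    n_iterations: int = 20_000
    n_burnin: int = 5_000
    thin: int = 5
    seed: int = 0
    rhat_threshold: float = 1.03

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the Gelman-Rubin statistic")
        if self.thin < 1 or self.n_burnin >= self.n_iterations:
            raise ValueError("bad thin/burn-in settings")

    @staticmethod
    def paper_scale(seed: int = 0) -> "MCMCConfig":
        return MCMCConfig(
            n_chains=5, n_iterations=1_200_000, n_burnin=200_000, thin=50, seed=seed
        )


@dataclass
class PosteriorSamples:
    """Labelled posterior draws: ``draws[chain, draw, param]`` on the
    natural parameter scale, with per-draw log-posterior and provenance."""

    names: list[str]
    draws: np.ndarray
    log_post: np.ndarray
    seed: int
    config: MCMCConfig
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    mode: str = "marginal"

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str, pooled: bool = True) -> np.ndarray:
        j = self.names.index(name)
        return self.draws[:, :, j].ravel() if pooled else self.draws[:, :, j]

    def map_draw(self) -> dict[str, float]:
        """Parameter values of the highest-log-posterior draw."""
        c, i = np.unravel_index(np.argmax(self.log_post), self.log_post.shape)
        return dict(zip(self.names, self.draws[c, i]))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy draws: chain, iteration, parameter, value."""
        c, n, p = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), n * p),
                "iteration": np.tile(np.repeat(np.arange(n), p), c),
                "parameter": np.tile(self.names, c * n),
                "value": self.draws.reshape(-1),
            }
        )

    def save_csv(self, path) -> None:
        """Tidy draws CSV; the per-draw log-posterior rides along as the
        pseudo-parameter ``__lp__``."""
        df = self.to_dataframe()
        c, n = self.log_post.shape
        lp = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), n),
                "iteration": np.tile(np.arange(n), c),
                "parameter": "__lp__",
                "value": self.log_post.reshape(-1),
            }
        )
        pd.concat([df, lp]).to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path, config: "MCMCConfig | None" = None) -> "PosteriorSamples":
        df = pd.read_csv(path)
        lp_df = df[df["parameter"] == "__lp__"]
        df = df[df["parameter"] != "__lp__"]
        names = list(dict.fromkeys(df["parameter"]))
        chains = sorted(df["chain"].unique())
        iters = sorted(df["iteration"].unique())
        wide = df.pivot_table(
            index=["chain", "iteration"], columns="parameter", values="value", sort=False
        )[names]
        draws = wide.to_numpy().reshape(len(chains), len(iters), len(names))
        lp = (
            lp_df.pivot_table(index="chain", columns="iteration", values="value").to_numpy()
            if len(lp_df)
            else np.zeros((len(chains), len(iters)))
        )
        cfg = config or MCMCConfig(n_chains=max(2, len(chains)), n_iterations=2, n_burnin=1)
        out = cls(names=names, draws=draws, log_post=lp, seed=cfg.seed, config=cfg)
        out.rhat = gelman_rubin(out) if len(chains) >= 2 and len(iters) >= 2 else {}
        return out


# ---------------------------------------------------------------------------
# Parameter vector layout
# ---------------------------------------------------------------------------


class _Layout:
    """Maps between the sampled vector, natural names and GrowthParameters."""

    def __init__(self, packed: PackedData):
        self.packed = packed
        S, Y = packed.n_sites, packed.n_years
        self.site_slice = slice(4, 4 + S)
        self.year_slice = slice(4 + S, 4 + S + Y)
        self.sig_site, self.sig_year, self.sig_resid = 4 + S + Y, 5 + S + Y, 6 + S + Y
        self.dim = 7 + S + Y
        self.natural_names = (
            ["l_inf", "beta", "alpha0", "alpha_treat"]
            + [f"eta_site[{s}]" for s in packed.site_names]
            + [f"eta_year[{y}]" for y in packed.year_names]
            + ["sigma_site", "sigma_year", "sigma_resid"]
        )

    def to_params(self, vec: np.ndarray) -> GrowthParameters:
        """Sampled vector (sigmas on log scale) -> GrowthParameters."""
        return GrowthParameters(
            l_inf=vec[0],
            beta=vec[1],
            alpha0=vec[2],
            alpha_treat=vec[3],
            eta_site=vec[self.site_slice].copy(),
            eta_year=vec[self.year_slice].copy(),
            sigma_site=float(np.exp(vec[self.sig_site])),
            sigma_year=float(np.exp(vec[self.sig_year])),
            sigma_resid=float(np.exp(vec[self.sig_resid])),
        )

    def to_natural(self, vec: np.ndarray) -> np.ndarray:
        out = vec.copy()
        for j in (self.sig_site, self.sig_year, self.sig_resid):
            out[..., j] = np.exp(out[..., j])
        return out

    def fixed_mask(self, fixed: dict | None) -> tuple[np.ndarray, np.ndarray]:
        """Resolve ``fixed`` (natural names -> values) into (mask, values)
        on the sampled scale. 'eta_site'/'eta_year' pin whole blocks."""
        mask = np.zeros(self.dim, dtype=bool)
        vals = np.zeros(self.dim)
        if not fixed:
            return mask, vals
        for key, v in fixed.items():
            if key == "eta_site":
                idx = list(range(self.site_slice.start, self.site_slice.stop))
            elif key == "eta_year":
                idx = list(range(self.year_slice.start, self.year_slice.stop))
            elif key in self.natural_names:
                idx = [self.natural_names.index(key)]
            else:
                raise KeyError(f"unknown parameter {key!r}")
            for j in idx:
                mask[j] = True
                vals[j] = np.log(v) if self.natural_names[j].startswith("sigma") else v
        return mask, vals


def _make_logpost(packed: PackedData, priors: PriorConfig, lay: _Layout):
    """Fast log-posterior on the sampled vector (marginal likelihood).

    Mirrors model.log_posterior plus the log-sigma Jacobian; the
    equivalence is pinned by a unit test.
    """
    x, z, t = packed.x, packed.z, packed.t
    idx = packed.comp_interval
    xc, zc, tc = x[idx], z[idx], t[idx]
    cs, cy, ch, cw = packed.comp_site, packed.comp_year, packed.comp_harvest, packed.comp_logw
    offsets = packed.offsets
    seg_len = np.diff(np.append(offsets, idx.size))
    x_bar = packed.x_bar
    lo_k, hi_k = priors.k_baseline_bounds
    lo_l, hi_l = priors.l_inf_bounds
    bound = priors.re_truncation
    rate = priors.sd_prior_rate
    sqrt2 = np.sqrt(2.0)

    def logpost(vec: np.ndarray) -> float:
        l_inf, beta, alpha0, alpha_t = vec[0], vec[1], vec[2], vec[3]
        eta_s = vec[lay.site_slice]
        eta_y = vec[lay.year_slice]
        ls_s, ls_y, ls_r = vec[lay.sig_site], vec[lay.sig_year], vec[lay.sig_resid]
        if not (lo_l < l_inf < hi_l) or not (np.log(lo_k + 1e-300) < alpha0 < np.log(hi_k)):
            return -np.inf
        if np.any(np.abs(eta_s) > bound) or np.any(np.abs(eta_y) > bound):
            return -np.inf
        if min(ls_s, ls_y, ls_r) < -30.0 or max(ls_s, ls_y, ls_r) > 30.0:
            return -np.inf  # sigma under/overflow: treat as out of support
        sig_s, sig_y, sig_r = np.exp(ls_s), np.exp(ls_y), np.exp(ls_r)
        # priors (+ Jacobian of the log-sigma transform: +log sigma each)
        lp = alpha0 - np.log(hi_k - lo_k) - np.log(hi_l - lo_l)
        lp += -0.5 * (alpha_t / priors.alpha_treat_sd) ** 2 - np.log(
            priors.alpha_treat_sd
        ) - 0.5 * _LOG_2PI
        lp += -0.5 * (beta / priors.beta_sd) ** 2 - np.log(priors.beta_sd) - 0.5 * _LOG_2PI
        lp += 3.0 * np.log(rate) - rate * (sig_s + sig_y + sig_r) + ls_s + ls_y + ls_r
        for eta, sig in ((eta_s, sig_s), (eta_y, sig_y)):
            lp += np.sum(-0.5 * (eta / sig) ** 2) - eta.size * (
                np.log(sig) + 0.5 * _LOG_2PI + np.log(erf(bound / (sig * sqrt2)))
            )
        # marginal likelihood over mixture components
        log_k = alpha0 + alpha_t * ch + eta_s[cs] + eta_y[cy]
        mu = (l_inf + beta * (xc - x_bar) - xc) * -np.expm1(-np.exp(log_k) * tc)
        r = (zc - mu) / sig_r
        comp = cw - 0.5 * r * r - ls_r - 0.5 * _LOG_2PI
        vmax = np.maximum.reduceat(comp, offsets)
        ll = vmax + np.log(np.add.reduceat(np.exp(comp - np.repeat(vmax, seg_len)), offsets))
        return float(lp + np.sum(ll))

    return logpost


def _gibbs_latents(packed: PackedData, vec, lay: _Layout, rng) -> np.ndarray:
    """Sample one mixture component per interval given current parameters
    (Gumbel-max over each interval's component block)."""
    p = lay.to_params(vec)
    log_k = (
        p.alpha0
        + p.alpha_treat * packed.comp_harvest
        + p.eta_site[packed.comp_site]
        + p.eta_year[packed.comp_year]
    )
    idx = packed.comp_interval
    mu = (p.l_inf + p.beta * (packed.x[idx] - packed.x_bar) - packed.x[idx]) * -np.expm1(
        -np.exp(log_k) * packed.t[idx]
    )
    r = (packed.z[idx] - mu) / p.sigma_resid
    score = packed.comp_logw - 0.5 * r * r + rng.gumbel(size=idx.size)
    seg_len = np.diff(np.append(packed.offsets, idx.size))
    vmax = np.maximum.reduceat(score, packed.offsets)
    is_max = score >= np.repeat(vmax, seg_len)
    cand = np.where(is_max, np.arange(idx.size), idx.size)
    return np.minimum.reduceat(cand, packed.offsets)


def _make_logpost_latent(packed: PackedData, priors: PriorConfig, lay: _Layout):
    """Joint log-posterior given an explicit latent component assignment."""
    from .model import log_prior

    def logpost(vec: np.ndarray, choice: np.ndarray) -> float:
        p = lay.to_params(vec)
        lp = log_prior(p, priors)
        if not np.isfinite(lp):
            return -np.inf
        lp += vec[lay.sig_site] + vec[lay.sig_year] + vec[lay.sig_resid]  # Jacobian
        cs = packed.comp_site[choice]
        cy = packed.comp_year[choice]
        ch = packed.comp_harvest[choice]
        log_k = p.alpha0 + p.alpha_treat * ch + p.eta_site[cs] + p.eta_year[cy]
        mu = (p.l_inf + p.beta * (packed.x - packed.x_bar) - packed.x) * -np.expm1(
            -np.exp(log_k) * packed.t
        )
        r = (packed.z - mu) / p.sigma_resid
        ll = np.sum(-0.5 * r * r) - packed.x.size * (
            np.log(p.sigma_resid) + 0.5 * _LOG_2PI
        )
        return float(lp + ll)

    return logpost


_INIT_RANGES = {
    "l_inf": (45.0, 75.0),
    "beta": (-0.3, 0.8),
    "alpha_treat": (-0.5, 0.8),
}


def _init_chain(lay: _Layout, rng, mask, fixed_vals) -> np.ndarray:
    vec = np.empty(lay.dim)
    vec[0] = rng.uniform(*_INIT_RANGES["l_inf"])
    vec[1] = rng.uniform(*_INIT_RANGES["beta"])
    vec[2] = np.log(rng.uniform(8e-4, 0.01))
    vec[3] = rng.uniform(*_INIT_RANGES["alpha_treat"])
    vec[lay.site_slice] = rng.uniform(-0.3, 0.3, lay.packed.n_sites)
    vec[lay.year_slice] = rng.uniform(-0.3, 0.3, lay.packed.n_years)
    vec[lay.sig_site] = np.log(rng.uniform(0.2, 1.0))
    vec[lay.sig_year] = np.log(rng.uniform(0.2, 1.0))
    vec[lay.sig_resid] = np.log(rng.uniform(0.8, 3.0))
    vec[mask] = fixed_vals[mask]
    return vec


def _proposal_scales(lay: _Layout) -> np.ndarray:
    s = np.full(lay.dim, 0.1)
    s[0] = 1.0  # l_inf, mm
    s[lay.sig_site] = s[lay.sig_year] = s[lay.sig_resid] = 0.2
    return s


def sample_posterior(
    data: ModelData | PackedData,
    priors: PriorConfig = PriorConfig(),
    mcmc: MCMCConfig = MCMCConfig(),
    fixed: dict | None = None,
    mode: str = "marginal",
) -> PosteriorSamples:
    """Draw from the posterior of the growth model.

    ``fixed`` pins parameters (by natural name; ``eta_site``/``eta_year``
    pin whole blocks) — used e.g. to reduce the model to a homogeneous
    Fabens fit. ``mode`` is 'marginal' (default) or 'latent' (explicit
    discrete latents with Gibbs updates). Deterministic given
    ``mcmc.seed``. Non-convergence (any R-hat above the threshold) is
    flagged on the result and warned about, never silently dropped.
    """
    if mode not in ("marginal", "latent"):
        raise ValueError(f"unknown mode {mode!r}")
    packed = data if isinstance(data, PackedData) else pack_model_data(data)
    if packed.n_intervals < 1:
        raise ValueError("need at least one interval")
    lay = _Layout(packed)
    mask, fixed_vals = lay.fixed_mask(fixed)
    free = np.flatnonzero(~mask)
    d = free.size
    if d == 0:
        raise ValueError("all parameters fixed; nothing to sample")

    f_marg = _make_logpost(packed, priors, lay)
    f_lat = _make_logpost_latent(packed, priors, lay) if mode == "latent" else None

    n_keep = (mcmc.n_iterations - mcmc.n_burnin) // mcmc.thin
    draws = np.empty((mcmc.n_chains, n_keep, lay.dim))
    lps = np.empty((mcmc.n_chains, n_keep))
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)

    target_accept = 0.234 if d > 4 else 0.35
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        vec = _init_chain(lay, rng, mask, fixed_vals)
        choice = _gibbs_latents(packed, vec, lay, rng) if mode == "latent" else None
        f = (lambda v: f_lat(v, choice)) if mode == "latent" else f_marg
        lp = f(vec)
        # re-draw inits landing in a -inf pocket (truncation edges)
        tries = 0
        while not np.isfinite(lp) and tries < 100:
            vec = _init_chain(lay, rng, mask, fixed_vals)
            lp = f(vec)
            tries += 1

        # translation moves ride the additive non-identifiability between
        # alpha0 and each random-effect block (the likelihood only sees
        # their sum; the priors decide the split). They change the prior
        # terms only, so acceptance is high and the ridge mixes fast.
        trans_dirs = []
        for block in (lay.site_slice, lay.year_slice):
            idx = np.arange(block.start, block.stop)
            if not mask[2] and not mask[idx].any():
                direction = np.zeros(lay.dim)
                direction[2] = 1.0
                direction[idx] = -1.0
                trans_dirs.append(direction)
        trans_log_s = [np.log(0.3)] * len(trans_dirs)
        # amplitude-rate scaling move: k *= e^delta while the increment
        # amplitude l_inf - x_bar + (beta-1)(x - x_bar) shrinks by e^-delta,
        # which leaves short-interval expected increments nearly unchanged.
        # Deterministic map for given delta; |Jacobian| = e^(-2 delta).
        scaling_move = not (mask[0] or mask[1] or mask[2])
        scale_log_s = np.log(0.2)
        x_bar = packed.x_bar

        scale0 = _proposal_scales(lay)[free]
        cov = np.diag(scale0**2)
        chol = np.linalg.cholesky(cov)
        log_lam = np.log(2.38 / np.sqrt(d))
        mean = vec[free].copy()
        kept = 0
        for it in range(mcmc.n_iterations):
            for _ in range(2):  # two global proposals per sweep
                step = np.exp(log_lam) * (chol @ rng.standard_normal(d))
                prop = vec.copy()
                prop[free] += step
                lp_prop = f(prop)
                log_acc = lp_prop - lp
                if np.log(rng.uniform()) < log_acc:
                    vec, lp = prop, lp_prop
            for j, direction in enumerate(trans_dirs):
                delta = np.exp(trans_log_s[j]) * rng.standard_normal()
                prop = vec + delta * direction
                lp_prop = f(prop)
                t_acc = lp_prop - lp
                if np.log(rng.uniform()) < t_acc:
                    vec, lp = prop, lp_prop
                if it < mcmc.n_burnin:
                    gam_t = (it + 1) ** -0.6
                    trans_log_s[j] += gam_t * (
                        min(1.0, np.exp(min(0.0, t_acc))) - 0.44
                    )
            if scaling_move:
                delta = np.exp(scale_log_s) * rng.standard_normal()
                prop = vec.copy()
                prop[0] = x_bar + (vec[0] - x_bar) * np.exp(-delta)
                prop[1] = 1.0 + (vec[1] - 1.0) * np.exp(-delta)
                prop[2] = vec[2] + delta
                lp_prop = f(prop)
                s_acc = lp_prop - lp - 2.0 * delta
                if np.log(rng.uniform()) < s_acc:
                    vec, lp = prop, lp_prop
                if it < mcmc.n_burnin:
                    scale_log_s += (it + 1) ** -0.6 * (
                        min(1.0, np.exp(min(0.0, s_acc))) - 0.44
                    )
            if mode == "latent":
                choice = _gibbs_latents(packed, vec, lay, rng)
                lp = f(vec)
            if it < mcmc.n_burnin:
                gam = (it + 1) ** -0.6
                acc_prob = min(1.0, np.exp(min(0.0, log_acc)))
                log_lam += gam * (acc_prob - target_accept)
                # classic equal-weight running covariance: steps stay large
                # along posterior ridges instead of tracking them locally
                w = 1.0 / (it + 2)
                delta = vec[free] - mean
                mean += w * delta
                cov += w * (np.outer(delta, delta) - cov)
                if (it + 1) % 200 == 0 and it > 100:
                    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(d))
            elif (it - mcmc.n_burnin) % mcmc.thin == mcmc.thin - 1 and kept < n_keep:
                draws[c, kept] = lay.to_natural(vec)
                lps[c, kept] = lp
                kept += 1

    samples = PosteriorSamples(
        names=lay.natural_names,
        draws=draws,
        log_post=lps,
        seed=mcmc.seed,
        config=mcmc,
        mode=mode,
    )
    samples.rhat = gelman_rubin(samples)
    free_names = [lay.natural_names[j] for j in free]
    samples.converged = all(
        samples.rhat[n] <= mcmc.rhat_threshold for n in free_names if np.isfinite(samples.rhat[n])
    )
    if not samples.converged:
        bad = {n: round(samples.rhat[n], 3) for n in free_names if samples.rhat[n] > mcmc.rhat_threshold}
        warnings.warn(f"chains not converged (R-hat > {mcmc.rhat_threshold}): {bad}")
    return samples


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------


def potential_scale_reduction(chains: np.ndarray) -> float:
    """Gelman-Rubin statistic for one parameter, ``chains[chain, draw]``.

    Classic between/within form: W = mean within-chain variance, B/n = the
    variance of chain means, pooled Vhat = (n-1)/n W + (1+1/m) B/n,
    R-hat = sqrt(Vhat / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    v_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    # B = 0 gives sqrt((n-1)/n) < 1, which is estimation noise: floor at 1
    return float(max(1.0, np.sqrt(v_hat / W)))


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Per-parameter potential scale reduction factor."""
    out = {}
    for j, name in enumerate(samples.names):
        arr = samples.draws[:, :, j]
        if np.allclose(arr, arr.flat[0]):  # pinned parameter
            out[name] = 1.0
        else:
            out[name] = potential_scale_reduction(arr)
    return out


@dataclass
class PosteriorSummary:
    """Posterior medians and central 95% credible intervals, plus the
    derived growth-rate ratio exp(alpha_treat) and Pr(alpha_treat > 0)."""

    table: pd.DataFrame
    growth_rate_ratio: dict[str, float]
    pr_alpha_treat_positive: float


def summarize_posterior(samples: PosteriorSamples) -> PosteriorSummary:
    """Summaries over pooled post-burn-in draws.

    The table carries median, 0.025/0.975 quantiles and the mean for every
    model parameter plus derived rows ``k_baseline`` (= exp(alpha0)) and
    ``growth_rate_ratio`` (= exp(alpha_treat), the multiplicative harvest
    effect on the growth coefficient).
    """
    if samples.n_draws == 0:
        raise ValueError("no draws to summarize")
    rows = {}
    for name in samples.names:
        x = samples.get(name)
        rows[name] = _qrow(x)
    if "alpha0" in samples.names:
        rows["k_baseline"] = _qrow(np.exp(samples.get("alpha0")))
    ratio, pr_pos = {}, float("nan")
    if "alpha_treat" in samples.names:
        alpha = samples.get("alpha_treat")
        # quantiles commute with the monotone exp transform; the mean does not
        ratio = {k: float(np.exp(v)) for k, v in rows["alpha_treat"].items()}
        ratio["mean"] = float(np.mean(np.exp(alpha)))
        rows["growth_rate_ratio"] = ratio
        pr_pos = float(np.mean(alpha > 0))
    table = pd.DataFrame(rows).T[["median", "q025", "q975", "mean"]]
    return PosteriorSummary(
        table=table,
        growth_rate_ratio=ratio,
        pr_alpha_treat_positive=pr_pos,
    )


def _qrow(x: np.ndarray) -> dict[str, float]:
    q = np.quantile(x, [0.5, 0.025, 0.975])
    return {
        "median": float(q[0]),
        "q025": float(q[1]),
        "q975": float(q[2]),
        "mean": float(np.mean(x)),
    }
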