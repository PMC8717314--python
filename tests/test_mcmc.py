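"""Sampler internals, convergence diagnostics and posterior summaries."""

import numpy as np
import pytest

from salgrowth import (
    MCMCConfig,
    PriorConfig,
    baci_interval_design,
    default_true_parameters,
    gelman_rubin,
    sample_posterior,
    simulate_intervals,
    summarize_posterior,
)
from salgrowth.mcmc import PosteriorSamples, _Layout, _make_logpost, potential_scale_reduction
from salgrowth.model import log_posterior, pack_model_data


@pytest.fixture(scope="module")
def packed_small():
    design = baci_interval_design(40, seed=10)
    data, _ = simulate_intervals(default_true_parameters(), design, seed=11)
    return pack_model_data(data)


class TestLogPostFastPath:
    def test_matches_reference_posterior_plus_jacobian(self, packed_small):
        """The sampler's inlined target must equal the reference
        log-posterior plus the log-sigma change-of-variables term."""
        lay = _Layout(packed_small)
        f = _make_logpost(packed_small, PriorConfig(), lay)
        rng = np.random.default_rng(0)
        for _ in range(20):
            vec = np.concatenate(
                [
                    [rng.uniform(40, 90)],
                    [rng.normal(0, 0.5)],
                    [np.log(rng.uniform(5e-4, 0.05))],
                    [rng.normal(0, 0.5)],
                    rng.uniform(-1.5, 1.5, packed_small.n_sites + packed_small.n_years),
                    np.log(rng.uniform(0.1, 2.0, 3)),
                ]
            )
            p = lay.to_params(vec)
            jac = vec[lay.sig_site] + vec[lay.sig_year] + vec[lay.sig_resid]
            ref = log_posterior(packed_small, p) + jac
            assert f(vec) == pytest.approx(ref, rel=1e-10)

    def test_out_of_support_is_minus_inf(self, packed_small):
        lay = _Layout(packed_small)
        f = _make_logpost(packed_small, PriorConfig(), lay)
        vec = np.zeros(lay.dim)
        vec[0] = 60.0
        vec[2] = np.log(0.15)  # k above uniform(0, 0.1) support
        assert f(vec) == -np.inf


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        chain = np.random.default_rng(0).normal(size=500)
        assert potential_scale_reduction(np.stack([chain, chain])) == pytest.approx(1.0)

    def test_separated_chains_match_direct_variance_computation(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        # independent computation straight from the B/W definitions
        m, n = chains.shape
        W = np.mean([np.var(c, ddof=1) for c in chains])
        B_over_n = np.var([c.mean() for c in chains], ddof=1)
        expect = np.sqrt(((n - 1) / n * W + (1 + 1 / m) * B_over_n) / W)
        got = potential_scale_reduction(chains)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got > 2.0  # far beyond any convergence threshold

    def test_well_mixed_chains_below_threshold(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 2000))
        assert potential_scale_reduction(chains) < 1.03

    def test_agrees_with_arviz_on_stationary_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 2000))
        ours = potential_scale_reduction(chains)
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0]))
        # different flavours (arviz rank-normalizes and splits) but both
        # must agree the chains are converged
        assert abs(ours - theirs) < 0.02
        assert ours < 1.03 and theirs < 1.03

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            potential_scale_reduction(np.zeros((1, 100)))


class TestSummaries:
    def _samples(self, draws_by_name):
        names = list(draws_by_name)
        arr = np.stack([np.asarray(draws_by_name[n], float) for n in names], axis=-1)
        arr = arr[None]  # single chain
        arr = np.concatenate([arr, arr])  # two identical chains
        cfg = MCMCConfig(n_chains=2, n_iterations=4, n_burnin=1, thin=1)
        return PosteriorSamples(
            names=names, draws=arr, log_post=np.zeros(arr.shape[:2]), seed=0, config=cfg
        )

    def test_median_of_1_to_100(self):
        base = {n: np.ones(100) for n in ("l_inf", "alpha_treat")}
        base["alpha_treat"] = np.arange(1.0, 101.0)
        s = summarize_posterior(self._samples(base))
        assert s.table.loc["alpha_treat", "median"] == pytest.approx(50.5)

    def test_all_positive_alpha_gives_pr_one(self):
        s = summarize_posterior(
            self._samples({"alpha_treat": np.abs(np.random.default_rng(0).normal(size=50)) + 0.01})
        )
        assert s.pr_alpha_treat_positive == 1.0

    def test_ratio_quantiles_are_exp_of_alpha_quantiles(self):
        draws = np.random.default_rng(1).normal(0.3, 0.2, size=400)
        s = summarize_posterior(self._samples({"alpha_treat": draws}))
        a = s.table.loc["alpha_treat"]
        r = s.growth_rate_ratio
        for key in ("median", "q025", "q975"):
            assert r[key] == pytest.approx(np.exp(a[key]), rel=1e-12)


class TestSamplePosterior:
    def test_same_seed_reproduces_draws_exactly(self):
        design = baci_interval_design(40, seed=20)
        data, _ = simulate_intervals(default_true_parameters(), design, seed=21)
        cfg = MCMCConfig(n_chains=2, n_iterations=1500, n_burnin=500, thin=5, seed=77)
        a = sample_posterior(data, mcmc=cfg)
        b = sample_posterior(data, mcmc=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.log_post, b.log_post)

    def test_random_effect_draws_respect_truncation(self, small_fit):
        _, _, fit = small_fit
        for name in fit.names:
            if name.startswith("eta_"):
                draws = fit.get(name)
                assert np.all(np.abs(draws) <= 2.0)

    def test_pinned_parameters_stay_pinned(self):
        design = baci_interval_design(40, seed=30)
        data, _ = simulate_intervals(default_true_parameters(), design, seed=31)
        cfg = MCMCConfig(n_chains=2, n_iterations=1200, n_burnin=400, thin=4, seed=5)
        fit = sample_posterior(data, mcmc=cfg, fixed={"beta": 0.0, "eta_site": 0.0})
        assert np.all(fit.get("beta") == 0.0)
        for s in ("C", "BA1", "BA2"):
            assert np.all(fit.get(f"eta_site[{s}]") == 0.0)

    def test_latent_mode_agrees_with_marginal_mode(self):
        """Explicit Gibbs-sampled discrete latents and analytic
        marginalization target the same posterior."""
        design = baci_interval_design(150, seed=40)
        data, _ = simulate_intervals(default_true_parameters(), design, seed=41)
        cfg = MCMCConfig(n_chains=2, n_iterations=8000, n_burnin=3000, thin=4, seed=6)
        marg = summarize_posterior(sample_posterior(data, mcmc=cfg, mode="marginal"))
        lat = summarize_posterior(sample_posterior(data, mcmc=cfg, mode="latent"))
        for name in ("alpha_treat", "sigma_resid"):
            assert marg.table.loc[name, "median"] == pytest.approx(
                lat.table.loc[name, "median"], abs=0.15
            )

    def test_degenerate_noiseless_data_concentrates_near_truth(self):
        """With increments exactly on the mean surface the posterior should
        pile up close to the generating curve."""
        tp = default_true_parameters(sigma_resid=1e-6)
        tp.beta = 0.4
        tp.sigma_site = 1e-8
        tp.sigma_year = 1e-8
        design = baci_interval_design(150, seed=50)
        data, _ = simulate_intervals(tp, design, seed=51)
        cfg = MCMCConfig(n_chains=2, n_iterations=6000, n_burnin=2500, thin=4, seed=7)
        fit = sample_posterior(
            data, mcmc=cfg, fixed={"eta_site": 0.0, "eta_year": 0.0,
                                   "sigma_site": 1e-3, "sigma_year": 1e-3}
        )
        m = fit.map_draw()
        assert m["l_inf"] == pytest.approx(tp.l_inf, rel=0.02)
        assert m["alpha_treat"] == pytest.approx(tp.alpha_treat, abs=0.05)

    def test_single_chain_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)


def test_samples_csv_roundtrip(tmp_path, small_fit):
    _, _, fit = small_fit
    p = tmp_path / "draws.csv"
    fit.save_csv(p)
    back = PosteriorSamples.load_csv(p)
    assert back.names == fit.names
    np.testing.assert_allclose(back.draws, fit.draws)
    np.testing.assert_allclose(back.log_post, fit.log_post)
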