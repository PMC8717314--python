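"""Increment equation, likelihood mixtures, priors and posterior assembly."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.stats import norm

from salgrowth import (
    GrowthParameters,
    HARVEST_MISSING,
    PriorConfig,
    expected_increment,
    growth_coefficient,
    interval_loglikelihood,
    log_posterior,
    mean_growth_curve,
    zero_increment_length,
)
from salgrowth.io_cmr import GrowthInterval, ModelData
from salgrowth.model import log_likelihood, log_prior, pack_model_data


def params(**kw):
    base = dict(
        l_inf=60.3,
        beta=0.5,
        alpha0=np.log(0.002),
        alpha_treat=np.log(1.4),
        eta_site=np.zeros(1),
        eta_year=np.zeros(3),
        sigma_site=0.35,
        sigma_year=0.46,
        sigma_resid=1.5,
    )
    base.update(kw)
    return GrowthParameters(**base)


def ode_increment(x, t, k, l_inf, beta, x_bar):
    """Independent oracle: integrate dL/dt = k (a_i - L), a_i = l_inf +
    beta (x - x_bar), from L(0) = x."""
    a_i = l_inf + beta * (x - x_bar)
    sol = solve_ivp(
        lambda _, L: k * (a_i - L), (0.0, t), [x], rtol=1e-11, atol=1e-12
    )
    return sol.y[0, -1] - x


class TestExpectedIncrement:
    def test_zero_cases(self):
        assert expected_increment(40, 0, 0.003, 60, 0.2, 50) == 0.0
        assert expected_increment(60, 500, 0.003, 60, 0.0, 50) == pytest.approx(0.0)

    def test_against_ode_oracle(self):
        val = expected_increment(40, 100, 0.003, 60.3, 0.2, 50)
        assert val == pytest.approx(4.743, abs=5e-4)
        oracle = ode_increment(40, 100, 0.003, 60.3, 0.2, 50)
        assert val == pytest.approx(oracle, rel=1e-8)

    @given(
        x=st.floats(25, 75),
        t=st.floats(1, 500),
        k=st.floats(1e-4, 0.01),
        l_inf=st.floats(50, 80),
        beta=st.floats(-0.5, 0.9),
    )
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing_in_start_length(self, x, t, k, l_inf, beta):
        x_bar = 50.0
        lo = expected_increment(x, t, k, l_inf, beta, x_bar)
        hi = expected_increment(x + 1.0, t, k, l_inf, beta, x_bar)
        assert hi < lo

    def test_crosses_zero_at_zero_increment_length(self):
        x0 = zero_increment_length(60.3, 0.5, 50.0)
        assert expected_increment(x0, 123, 0.002, 60.3, 0.5, 50.0) == pytest.approx(0.0, abs=1e-10)
        assert expected_increment(x0 - 1, 123, 0.002, 60.3, 0.5, 50.0) > 0
        assert expected_increment(x0 + 1, 123, 0.002, 60.3, 0.5, 50.0) < 0


class TestGrowthCoefficient:
    def test_baseline_identity(self):
        assert growth_coefficient(np.log(0.002), 0.7, 0, 0.0, 0.0) == pytest.approx(0.002)

    def test_truncation_bound_is_sevenfold(self):
        k0 = growth_coefficient(np.log(0.002), 0.0, 0, 0.0, 0.0)
        k2 = growth_coefficient(np.log(0.002), 0.0, 0, 2.0, 0.0)
        assert k2 / k0 == pytest.approx(np.e**2, rel=1e-12)  # ~7.39x

    def test_harvest_effect_multiplies(self):
        k0 = growth_coefficient(np.log(0.002), 0.29, 0)
        k1 = growth_coefficient(np.log(0.002), 0.29, 1)
        assert k1 / k0 == pytest.approx(np.exp(0.29), rel=1e-12)


class TestZeroIncrementLength:
    def test_homogeneous_case_is_l_inf(self):
        assert zero_increment_length(60.3, 0.0, 50.0) == 60.3

    def test_matches_root_finding_oracle(self):
        from scipy.optimize import brentq

        root = brentq(
            lambda x: expected_increment(x, 100, 0.002, 60.3, 0.5, 50.0), 40, 100
        )
        assert zero_increment_length(60.3, 0.5, 50.0) == pytest.approx(root, rel=1e-10)
        assert zero_increment_length(60.3, 0.5, 50.0) == pytest.approx(70.6, abs=0.01)

    def test_diverges_towards_beta_one(self):
        vals = [zero_increment_length(60.3, b, 50.0) for b in (0.9, 0.99, 0.999)]
        assert vals[0] < vals[1] < vals[2]
        with pytest.raises(ValueError):
            zero_increment_length(60.3, 1.0, 50.0)


class TestMeanGrowthCurve:
    def test_origin_asymptote_and_bound(self):
        p = params()
        ages = np.linspace(0, 36500, 500)
        L = mean_growth_curve(p, 0, ages)
        assert L[0] == 0.0
        assert L[-1] == pytest.approx(p.l_inf, rel=1e-3)
        assert np.all(np.diff(L) >= 0) and np.all(L <= p.l_inf)

    def test_harvest_curve_is_time_rescaled_control_curve(self):
        p = params()
        ages = np.linspace(10, 3000, 50)
        ratio = np.exp(p.alpha_treat)
        treated = mean_growth_curve(p, 1, ages / ratio)
        control = mean_growth_curve(p, 0, ages)
        np.testing.assert_allclose(treated, control, rtol=1e-12)


def iv(x=45.0, z=3.0, t=120, site="s", years=(2015,), harvest=0):
    return GrowthInterval("i", site, x, z, t, tuple(years), harvest)


class TestIntervalLoglikelihood:
    def test_single_component_matches_gaussian_density(self):
        p = params()
        interval = iv()
        mu = expected_increment(45.0, 120, growth_coefficient(p.alpha0, p.alpha_treat, 0), p.l_inf, p.beta, 50.0)
        expect = norm.logpdf(3.0, mu, p.sigma_resid)
        assert interval_loglikelihood(interval, p, 50.0) == pytest.approx(expect, rel=1e-12)

    def test_missing_harvest_is_equal_mixture(self):
        p = params()
        interval = iv(harvest=HARVEST_MISSING)
        f = [
            np.exp(interval_loglikelihood(iv(harvest=h), p, 50.0)) for h in (0, 1)
        ]
        expect = np.log(0.5 * f[0] + 0.5 * f[1])
        assert interval_loglikelihood(interval, p, 50.0) == pytest.approx(expect, rel=1e-12)

    def test_marginal_lies_between_conditional_densities(self):
        p = params()
        conds = [interval_loglikelihood(iv(harvest=h), p, 50.0) for h in (0, 1)]
        marg = interval_loglikelihood(iv(harvest=HARVEST_MISSING), p, 50.0)
        assert min(conds) <= marg <= max(conds)

    def test_two_year_mixture_matches_monte_carlo_oracle(self):
        p = params(eta_year=np.array([0.4, -0.3, 0.0]))
        interval = iv(years=(2014, 2015))
        year_index = {2014: 0, 2015: 1, 2016: 2}
        exact = interval_loglikelihood(interval, p, 50.0, year_index=year_index)
        rng = np.random.default_rng(1)
        n = 10**6
        pick = rng.integers(0, 2, size=n)
        k = growth_coefficient(
            p.alpha0, p.alpha_treat, 0, 0.0, p.eta_year[pick]
        )
        mu = expected_increment(45.0, 120, k, p.l_inf, p.beta, 50.0)
        dens = norm.pdf(3.0, mu, p.sigma_resid)
        mc, se = dens.mean(), dens.std(ddof=1) / np.sqrt(n)
        assert abs(np.exp(exact) - mc) < 3 * se

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            interval_loglikelihood(iv(), params(sigma_resid=0.0), 50.0)


class TestLogPosterior:
    def test_outside_k_prior_support_is_minus_inf(self):
        data = ModelData([iv()])
        assert log_posterior(data, params(alpha0=np.log(0.15))) == -np.inf

    def test_single_interval_additivity(self):
        data = ModelData([iv(years=(2015,))])
        p = params(eta_year=np.zeros(1))
        lp = log_posterior(data, p)
        prior = log_prior(p)
        like = interval_loglikelihood(data.intervals[0], p, data.x_bar_mm)
        assert lp == pytest.approx(prior + like, rel=1e-12)

    def test_small_dataset_matches_term_by_term_summation(self):
        rng = np.random.default_rng(3)
        intervals = [
            iv(
                x=float(rng.uniform(35, 60)),
                z=float(rng.normal(3, 1)),
                t=int(rng.integers(30, 300)),
                site=s,
                years=(y,),
                harvest=h,
            )
            for s, y, h in [("a", 2014, 0), ("a", 2015, 1), ("b", 2015, 0), ("b", 2016, 1), ("a", 2016, 0)]
        ]
        data = ModelData(intervals)
        p = params(eta_site=np.array([0.1, -0.2]), eta_year=np.array([0.0, 0.3, -0.1]))
        total = log_prior(p) + sum(
            interval_loglikelihood(i, p, data.x_bar_mm, data.site_index, data.year_index)
            for i in intervals
        )
        assert log_posterior(data, p) == pytest.approx(total, rel=1e-12)

    def test_eta_outside_truncation_is_minus_inf(self):
        data = ModelData([iv()])
        p = params(eta_site=np.array([2.5]))
        assert log_posterior(data, p) == -np.inf

    def test_packed_likelihood_matches_interval_sum(self):
        rng = np.random.default_rng(8)
        intervals = [
            iv(
                x=float(rng.uniform(35, 60)),
                z=float(rng.normal(2, 2)),
                t=int(rng.integers(30, 300)),
                site=["a", "b"][int(rng.integers(2))],
                years=(2014, 2015) if rng.uniform() < 0.3 else (int(rng.integers(2014, 2017)),),
                harvest=HARVEST_MISSING if rng.uniform() < 0.2 else int(rng.integers(2)),
            )
            for _ in range(30)
        ]
        data = ModelData(intervals)
        packed = pack_model_data(data)
        p = params(eta_site=np.array([0.2, -0.1]), eta_year=np.array([0.1, -0.3, 0.2]))
        direct = sum(
            interval_loglikelihood(i, p, data.x_bar_mm, data.site_index, data.year_index)
            for i in intervals
        )
        assert log_likelihood(packed, p) == pytest.approx(direct, rel=1e-12)
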