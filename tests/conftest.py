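"""Shared fixtures: toy capture sets and simulate-fit replicates.

The replicate fits are session-scoped because both the recovery and the
posterior-predictive calibration checks consume the same ten
simulate-and-fit experiments.
"""

import datetime as dt
import warnings

import numpy as np
import pytest

from salgrowth import (
    CaptureRecord,
    MCMCConfig,
    SiteMetadata,
    baci_interval_design,
    default_true_parameters,
    sample_posterior,
    simulate_intervals,
)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="chains not converged")
        yield


@pytest.fixture
def toy_sites():
    return [
        SiteMetadata("C", "control"),
        SiteMetadata("T1", "treatment", dt.date(2015, 1, 15)),
        SiteMetadata("T2", "treatment", dt.date(2016, 1, 15)),
    ]


def capture(ind, site, date, svl, **kw):
    return CaptureRecord(
        individual_id=ind, site_id=site, capture_date=date, svl_mm=svl, **kw
    )


@pytest.fixture
def small_fit():
    """A quick fit on a small simulated dataset, for smoke-level checks."""
    design = baci_interval_design(150, seed=42)
    data, truth = simulate_intervals(default_true_parameters(), design, seed=43)
    fit = sample_posterior(
        data,
        mcmc=MCMCConfig(n_chains=2, n_iterations=6000, n_burnin=2000, thin=4, seed=44),
    )
    return data, truth, fit


@pytest.fixture(scope="session")
def replicate_fits():
    """Ten simulate-and-fit replicates at the study's design scale:
    600 intervals over 3 sites x 3 years, true growth-rate ratio 1.4,
    desk-scale chains. Shared by recovery and calibration checks."""
    true_params = default_true_parameters()
    out = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="chains not converged")
        for r in range(10):
            design = baci_interval_design(600, seed=100 + r)
            data, truth = simulate_intervals(true_params, design, seed=200 + r)
            fit = sample_posterior(data, mcmc=MCMCConfig(seed=300 + r))
            out.append((data, truth, fit))
    return out
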