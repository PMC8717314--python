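"""Figures, tables and run manifests for the analysis drivers.

Figures are analogues of the study's presentation — growth increment
against start length, population mean growth curves, metamorph size box
plots, and the log-log mass-length scatter — not pixel replicas; the
tabular outputs are the contract surface.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import os
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io_cmr import HARVEST_MISSING, CaptureRecord, ModelData, SiteMetadata
from .mcmc import PosteriorSamples
from .model import expected_increment, growth_coefficient

__all__ = [
    "write_manifest",
    "fig_increment_vs_length",
    "fig_growth_curves",
    "fig_metamorph_boxes",
    "fig_condition_scatter",
]


def write_manifest(path, seed: int, config: dict | None = None, inputs: Sequence = ()) -> dict:
    """Record what a run needs to be reproduced: seed, config snapshot,
    SHA-256 of each input file, package version, timestamp."""
    from . import __version__

    manifest = {
        "seed": int(seed),
        "config": config or {},
        "inputs": {
            str(p): hashlib.sha256(open(p, "rb").read()).hexdigest() for p in inputs
        },
        "package_version": __version__,
        "written_at": dt.datetime.now().isoformat(timespec="seconds"),
    }
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _posterior_curves(samples: PosteriorSamples, x_grid, x_bar, harvest, n_draws=200):
    """Daily expected increment curves (mm/day) over a length grid for a
    thinned set of posterior draws."""
    total = samples.n_chains * samples.n_draws
    stride = max(1, total // n_draws)
    get = lambda n: samples.get(n)[::stride]
    l_inf, beta = get("l_inf"), get("beta")
    k = growth_coefficient(get("alpha0"), get("alpha_treat"), harvest)
    # per-day rate: d mu / dt at t=0 is k * (asymptote - x)
    return (
        (l_inf[:, None] + beta[:, None] * (x_grid - x_bar) - x_grid) * k[:, None]
    )


def fig_increment_vs_length(
    samples: PosteriorSamples, data: ModelData, path, n_draws: int = 200
) -> None:
    """Observed daily increments (z/T) against start length with posterior
    median and 95% bands of the expected daily rate, control vs post-harvest."""
    x_grid = np.linspace(25, 80, 120)
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {0: "#d4a017", 1: "#4b0082"}
    for iv in data.intervals:
        h = iv.harvest_state
        c = colors[0] if h in (0, HARVEST_MISSING) else colors[1]
        ax.plot(iv.x_svl_mm, iv.z_mm / iv.t_days, "o", ms=2.5, alpha=0.35, color=c)
    for h, label in ((0, "control / pre-harvest"), (1, "post-harvest")):
        curves = _posterior_curves(samples, x_grid, data.x_bar_mm, h, n_draws)
        med = np.median(curves, axis=0)
        lo, hi = np.quantile(curves, [0.025, 0.975], axis=0)
        ax.plot(x_grid, med, color=colors[h], lw=2, label=label)
        ax.fill_between(x_grid, lo, hi, color=colors[h], alpha=0.2, lw=0)
    ax.axhline(0.0, ls=":", color="gray", lw=1)
    ax.set_xlabel("snout-vent length at start of interval (mm)")
    ax.set_ylabel("growth increment (mm/day)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fig_growth_curves(samples: PosteriorSamples, path, max_age_days: float = 3650) -> None:
    """Population mean length-at-age curves, control vs post-harvest, with
    95% credible bands."""
    ages = np.linspace(0, max_age_days, 200)
    total = samples.n_chains * samples.n_draws
    stride = max(1, total // 300)
    l_inf = samples.get("l_inf")[::stride]
    alpha0 = samples.get("alpha0")[::stride]
    alpha_t = samples.get("alpha_treat")[::stride]
    fig, ax = plt.subplots(figsize=(6, 4))
    styles = {0: ("#d4a017", "--", "control / pre-harvest"), 1: ("#4b0082", "-", "post-harvest")}
    for h, (color, ls, label) in styles.items():
        k = np.exp(alpha0 + alpha_t * h)
        curves = l_inf[:, None] * -np.expm1(-k[:, None] * ages)
        med = np.median(curves, axis=0)
        lo, hi = np.quantile(curves, [0.025, 0.975], axis=0)
        ax.plot(ages / 365.25, med, ls, color=color, lw=2, label=label)
        ax.fill_between(ages / 365.25, lo, hi, color=color, alpha=0.2, lw=0)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("snout-vent length (mm)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fig_metamorph_boxes(
    records: Sequence[CaptureRecord], sites: Sequence[SiteMetadata], path,
    month: int = 6, svl_threshold: float = 45.0,
) -> None:
    """Box plots of June metamorph size per site-year, shaded by harvest."""
    from .body_size import _is_postharvest

    site_map = {s.site_id: s for s in sites}
    groups: dict[tuple, list[float]] = {}
    for r in records:
        if r.capture_date.month != month or r.svl_mm > svl_threshold:
            continue
        groups.setdefault((r.site_id, r.capture_date.year), []).append(r.svl_mm)
    keys = sorted(groups)
    fig, ax = plt.subplots(figsize=(7, 4))
    data = [groups[k] for k in keys]
    bp = ax.boxplot(data, patch_artist=True, labels=[f"{s}\n{y}" for s, y in keys])
    for patch, (s, y) in zip(bp["boxes"], keys):
        post = _is_postharvest(site_map[s], y, month)
        patch.set_facecolor("#4b0082" if post else "#d4a017")
        patch.set_alpha(0.6)
    ax.set_ylabel("snout-vent length (mm)")
    ax.set_title("June metamorph body size (purple = post-harvest)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fig_condition_scatter(
    records: Sequence[CaptureRecord], sites: Sequence[SiteMetadata], path,
    exclude_gravid: bool = True,
) -> None:
    """Log mass against log SVL, colored control vs post-harvest."""
    from .body_size import _is_postharvest

    site_map = {s.site_id: s for s in sites}
    fig, ax = plt.subplots(figsize=(5.5, 4))
    pts = {"control": [], "treatment": []}
    for r in records:
        if r.mass_g is None or (exclude_gravid and r.gravid):
            continue
        post = _is_postharvest(site_map[r.site_id], r.capture_date.year, r.capture_date.month)
        pts["treatment" if post else "control"].append((np.log(r.svl_mm), np.log(r.mass_g)))
    for label, color in (("control", "#d4a017"), ("treatment", "#4b0082")):
        if pts[label]:
            xy = np.array(pts[label])
            ax.plot(xy[:, 0], xy[:, 1], "o", ms=2.5, alpha=0.4, color=color, label=label)
    ax.set_xlabel("log snout-vent length (mm)")
    ax.set_ylabel("log mass (g)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
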