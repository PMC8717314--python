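"""Ancillary body-size analyses.

Two analyses accompany the growth model: (1) a descriptive comparison of
recently metamorphosed animals (at most 45 mm snout-vent length, captured
in June of each year) across site-years, contrasting pre- and post-harvest
cohorts at the treatment sites; and (2) a body-condition test — ordinary
least squares of log(mass) on log(SVL) pooled over captures, with a
one-way ANOVA on the *ranked* residuals between treatment groups. Ranking
makes the comparison robust to the residual distribution (and invariant to
monotone transforms). Gravid females are excluded from the condition
analysis by default because clutch mass inflates body condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_cmr import CaptureRecord, SiteMetadata

__all__ = [
    "MetamorphSummary",
    "ConditionResult",
    "metamorph_summary",
    "condition_anova",
]

JUNE = 6
METAMORPH_SVL_MM = 45.0


@dataclass
class MetamorphSummary:
    """Per-(site, year) size summaries of recent metamorphs and, for each
    treatment site, the post-minus-pre mean difference in mm."""

    table: pd.DataFrame  # site, year, harvested, n, mean, q25, median, q75
    shifts_mm: dict[str, float] = field(default_factory=dict)


def _is_postharvest(site: SiteMetadata, year: int, month: int) -> bool:
    if site.role != "treatment":
        return False
    h = site.harvest_date
    return (year, month) >= (h.year, h.month)


def metamorph_summary(
    records: Iterable[CaptureRecord],
    sites: Iterable[SiteMetadata],
    month: int = JUNE,
    svl_threshold: float = METAMORPH_SVL_MM,
) -> MetamorphSummary:
    """Summarize recent-metamorph body size per site-year.

    Filters captures to ``month`` and SVL <= ``svl_threshold``; empty
    site-year groups appear with n = 0 and no statistics. The shift for a
    treatment site is mean(post-harvest SVL) - mean(pre-harvest SVL),
    pooled over that site's years.
    """
    site_map = {s.site_id: s for s in sites}
    rows = []
    for r in records:
        if r.capture_date.month != month or r.svl_mm > svl_threshold:
            continue
        site = site_map[r.site_id]
        rows.append(
            {
                "site": r.site_id,
                "year": r.capture_date.year,
                "svl_mm": r.svl_mm,
                "post": _is_postharvest(site, r.capture_date.year, month),
            }
        )
    df = pd.DataFrame(rows, columns=["site", "year", "svl_mm", "post"]).astype(
        {"svl_mm": float, "post": bool}
    )
    summaries = []
    for (site_id, year), g in df.groupby(["site", "year"]):
        q = g["svl_mm"].quantile([0.25, 0.5, 0.75])
        summaries.append(
            {
                "site": site_id,
                "year": year,
                "harvested": bool(g["post"].iloc[0]),
                "n": len(g),
                "mean_svl_mm": g["svl_mm"].mean(),
                "q25": q[0.25],
                "median": q[0.5],
                "q75": q[0.75],
            }
        )
    table = pd.DataFrame(
        summaries,
        columns=["site", "year", "harvested", "n", "mean_svl_mm", "q25", "median", "q75"],
    )
    shifts = {}
    for s in site_map.values():
        if s.role != "treatment":
            continue
        g = df[df["site"] == s.site_id]
        pre, post = g[~g["post"]]["svl_mm"], g[g["post"]]["svl_mm"]
        if len(pre) and len(post):
            shifts[s.site_id] = float(post.mean() - pre.mean())
    return MetamorphSummary(table=table, shifts_mm=shifts)


@dataclass
class ConditionResult:
    f_statistic: float
    df_num: int
    df_denom: int
    p_value: float
    r_squared: float  # of the pooled log(mass) ~ log(SVL) regression
    n: int
    group_rank_means: dict[str, float] = field(default_factory=dict)


def condition_anova(
    records: Sequence[CaptureRecord],
    sites: Iterable[SiteMetadata],
    exclude_gravid: bool = True,
) -> ConditionResult:
    """Body-condition comparison between treatment groups.

    A capture belongs to the 'treatment' group if it is a post-harvest
    capture at a treatment site, else 'control' (controls and pre-harvest
    captures pooled). Procedure: OLS of log(mass) on log(SVL) over all
    included captures; residuals ranked (average ranks on ties); one-way
    ANOVA of the ranks between groups. Requires mass; records without mass
    (and gravid females, unless ``exclude_gravid=False``) are dropped.
    """
    site_map = {s.site_id: s for s in sites}
    log_mass, log_svl, group = [], [], []
    for r in records:
        if r.mass_g is None:
            continue
        if exclude_gravid and r.gravid:
            continue
        site = site_map[r.site_id]
        post = _is_postharvest(site, r.capture_date.year, r.capture_date.month)
        log_mass.append(np.log(r.mass_g))
        log_svl.append(np.log(r.svl_mm))
        group.append("treatment" if post else "control")
    n = len(log_mass)
    groups = sorted(set(group))
    if n < 3 or len(groups) < 2:
        raise ValueError(
            f"condition ANOVA needs >=3 records with mass in >=2 groups "
            f"(got n={n}, groups={groups})"
        )
    X = sm.add_constant(np.asarray(log_svl))
    fit = sm.OLS(np.asarray(log_mass), X).fit()
    ranks = stats.rankdata(fit.resid)  # average ranks for ties
    by_group = [ranks[np.asarray(group) == g] for g in groups]
    f_stat, p = stats.f_oneway(*by_group)
    return ConditionResult(
        f_statistic=float(f_stat),
        df_num=len(groups) - 1,
        df_denom=n - len(groups),
        p_value=float(p),
        r_squared=float(fit.rsquared),
        n=n,
        group_rank_means={g: float(np.mean(v)) for g, v in zip(groups, by_group)},
    )
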