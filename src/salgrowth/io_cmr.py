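"""Capture-mark-recapture table handling and growth-interval construction.

Reads capture and site-metadata CSVs, validates them, applies the minimum
recapture-gap rule (captures closer than ``min_gap_days`` carry no usable
growth signal and are dropped), and pairs successive retained captures of
each individual into growth intervals — the observation unit of the
growth-increment model.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaptureRecord",
    "SiteMetadata",
    "GrowthInterval",
    "ModelData",
    "FormatError",
    "ValidationError",
    "read_captures",
    "read_sites",
    "build_growth_intervals",
    "compute_sample_mean_svl",
]

HARVEST_MISSING = -1  # sentinel for an interval straddling the harvest date


class FormatError(ValueError):
    """The file does not have the required columns/structure."""


class ValidationError(ValueError):
    """One or more rows violate a field invariant; message lists row numbers."""


@dataclass(frozen=True)
class CaptureRecord:
    """One processed capture of one marked salamander.

    ``stage`` is 'juvenile' for animals at or below 45 mm snout-vent length
    (recently metamorphosed, under a year past metamorphosis) and 'adult'
    otherwise.
    """

    individual_id: str
    site_id: str
    capture_date: dt.date
    svl_mm: float
    mass_g: float | None = None
    stage: str | None = None
    gravid: bool | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if not self.svl_mm > 0:
            raise ValueError(f"svl_mm must be positive, got {self.svl_mm}")
        if self.mass_g is not None and not self.mass_g > 0:
            raise ValueError(f"mass_g must be positive, got {self.mass_g}")


@dataclass(frozen=True)
class SiteMetadata:
    """Role of a study site: unharvested control or harvested treatment."""

    site_id: str
    role: str  # 'control' | 'treatment'
    harvest_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.role not in ("control", "treatment"):
            raise ValueError(f"role must be control|treatment, got {self.role!r}")
        if self.role == "treatment" and self.harvest_date is None:
            raise ValueError(f"treatment site {self.site_id} needs a harvest_date")
        if self.role == "control" and self.harvest_date is not None:
            raise ValueError(f"control site {self.site_id} must not have a harvest_date")


@dataclass(frozen=True)
class GrowthInterval:
    """One recapture pair: start length X, increment Z, elapsed time T.

    ``harvest_state`` is 0 (pre-harvest or control), 1 (post-harvest) or
    ``HARVEST_MISSING`` when the interval straddles the site's harvest date,
    in which case the likelihood marginalizes it over a Bernoulli(0.5) prior.
    ``years_spanned`` lists every calendar year the interval touches; the
    year random effect for a multi-year interval is an equal-probability
    categorical mixture over them.
    """

    individual_id: str
    site_id: str
    x_svl_mm: float
    z_mm: float
    t_days: int
    years_spanned: tuple[int, ...]
    harvest_state: int

    def __post_init__(self) -> None:
        if self.t_days <= 0:
            raise ValueError("t_days must be positive")
        if not self.years_spanned:
            raise ValueError("years_spanned must be non-empty")
        if self.harvest_state not in (0, 1, HARVEST_MISSING):
            raise ValueError(f"bad harvest_state {self.harvest_state}")


@dataclass
class ModelData:
    """The growth-increment dataset the model consumes.

    ``x_bar_mm`` is the sample mean of interval start lengths, the centring
    constant E(X) of the Wang asymptote approximation. ``site_index`` and
    ``year_index`` map site ids / calendar years to contiguous random-effect
    indices.
    """

    intervals: list[GrowthInterval]
    x_bar_mm: float = field(init=False)
    site_index: dict[str, int] = field(init=False)
    year_index: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("ModelData requires at least one interval")
        self.x_bar_mm = compute_sample_mean_svl(self.intervals)
        sites = sorted({iv.site_id for iv in self.intervals})
        years = sorted({y for iv in self.intervals for y in iv.years_spanned})
        self.site_index = {s: i for i, s in enumerate(sites)}
        self.year_index = {y: i for i, y in enumerate(years)}

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def n_sites(self) -> int:
        return len(self.site_index)

    @property
    def n_years(self) -> int:
        return len(self.year_index)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "individual_id": iv.individual_id,
                "site": iv.site_id,
                "x_svl_mm": iv.x_svl_mm,
                "z_mm": iv.z_mm,
                "t_days": iv.t_days,
                "year_first": iv.years_spanned[0],
                "year_last": iv.years_spanned[-1],
                "harvest_state": (
                    np.nan if iv.harvest_state == HARVEST_MISSING else iv.harvest_state
                ),
            }
            for iv in self.intervals
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ModelData":
        df = pd.read_csv(path)
        intervals = []
        for _, r in df.iterrows():
            hs = r["harvest_state"]
            hs = HARVEST_MISSING if pd.isna(hs) else int(hs)
            intervals.append(
                GrowthInterval(
                    individual_id=str(r["individual_id"]),
                    site_id=str(r["site"]),
                    x_svl_mm=float(r["x_svl_mm"]),
                    z_mm=float(r["z_mm"]),
                    t_days=int(r["t_days"]),
                    years_spanned=tuple(range(int(r["year_first"]), int(r["year_last"]) + 1)),
                    harvest_state=hs,
                )
            )
        return cls(intervals)


_CANONICAL_COLUMNS = {
    "individual_id": "individual_id",
    "site": "site",
    "date": "date",
    "svl_mm": "svl_mm",
    "mass_g": "mass_g",
    "stage": "stage",
    "gravid": "gravid",
    "sex": "sex",
}
_REQUIRED = ("individual_id", "site", "date", "svl_mm")


def _parse_bool(v) -> bool | None:
    if pd.isna(v):
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"unparseable boolean {v!r}")


def read_captures(path, schema: Mapping[str, str] | None = None) -> list[CaptureRecord]:
    """Read a capture table CSV into validated records, preserving row order.

    ``schema`` maps canonical column names (``individual_id``, ``site``,
    ``date``, ``svl_mm``, ``mass_g``, ``stage``, ``gravid``, ``sex``) to the
    file's column names. Missing optional columns leave the corresponding
    fields unset. Raises :class:`FormatError` for missing required columns
    and :class:`ValidationError` naming offending rows (1-based, excluding
    the header) for bad values.
    """
    colmap = dict(_CANONICAL_COLUMNS)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    missing = [colmap[c] for c in _REQUIRED if colmap[c] not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    records: list[CaptureRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()

        def get(canon):
            col = colmap[canon]
            return row.get(col) if col in df.columns else None

        try:
            date = pd.Timestamp(get("date")).date()
        except (ValueError, TypeError):
            errors.append(f"row {i}: unparseable date {get('date')!r}")
            continue
        try:
            svl = float(get("svl_mm"))
            mass = get("mass_g")
            mass = None if mass is None or pd.isna(mass) else float(mass)
            stage = get("stage")
            stage = None if stage is None or pd.isna(stage) else str(stage)
            sex = get("sex")
            sex = None if sex is None or pd.isna(sex) else str(sex)
            records.append(
                CaptureRecord(
                    individual_id=str(get("individual_id")),
                    site_id=str(get("site")),
                    capture_date=date,
                    svl_mm=svl,
                    mass_g=mass,
                    stage=stage,
                    gravid=_parse_bool(get("gravid")),
                    sex=sex,
                )
            )
        except (ValueError, TypeError) as e:
            errors.append(f"row {i}: {e}")
    if errors:
        raise ValidationError("; ".join(errors))
    return records


def read_sites(path) -> list[SiteMetadata]:
    """Read site metadata CSV (columns: site, role, harvest_date)."""
    df = pd.read_csv(path)
    for col in ("site", "role"):
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    out = []
    for _, r in df.iterrows():
        hd = r.get("harvest_date")
        hd = None if hd is None or pd.isna(hd) else pd.Timestamp(hd).date()
        out.append(SiteMetadata(site_id=str(r["site"]), role=str(r["role"]), harvest_date=hd))
    return out


def _harvest_state(site: SiteMetadata, start: dt.date, end: dt.date) -> int:
    # A capture on the harvest date itself counts as post-harvest; the
    # missing state is strict straddling (start < harvest < end), so an
    # interval ending exactly on the harvest date grew entirely pre-harvest.
    if site.role == "control":
        return 0
    h = site.harvest_date
    if start >= h:
        return 1
    if end <= h:
        return 0
    return HARVEST_MISSING


def retained_captures(
    captures: Sequence[CaptureRecord], min_gap_days: int = 21
) -> list[CaptureRecord]:
    """Greedy forward retention of one individual's captures, date order.

    Keep the first capture; keep each later capture only if at least
    ``min_gap_days`` after the previously *kept* one.
    """
    kept: list[CaptureRecord] = []
    for rec in sorted(captures, key=lambda r: r.capture_date):
        if not kept or (rec.capture_date - kept[-1].capture_date).days >= min_gap_days:
            kept.append(rec)
    return kept


def build_growth_intervals(
    records: Iterable[CaptureRecord],
    sites: Iterable[SiteMetadata],
    min_gap_days: int = 21,
) -> ModelData:
    """Apply the recapture-gap filter and pair retained captures into intervals.

    Per individual, captures are scanned in date order with greedy retention
    (see :func:`retained_captures`); successive retained captures form
    intervals with X = earlier SVL, Z = later − earlier (negative allowed —
    measurement error can shrink an animal on paper), T = days elapsed.
    Individuals with fewer than two retained captures contribute nothing.
    """
    site_map = {s.site_id: s for s in sites}
    by_ind: dict[str, list[CaptureRecord]] = {}
    for rec in records:
        if rec.site_id not in site_map:
            raise KeyError(f"unknown site_id {rec.site_id!r}")
        by_ind.setdefault(rec.individual_id, []).append(rec)

    intervals: list[GrowthInterval] = []
    for ind_id in sorted(by_ind):
        kept = retained_captures(by_ind[ind_id], min_gap_days)
        for a, b in zip(kept[:-1], kept[1:]):
            site = site_map[a.site_id]
            years = tuple(range(a.capture_date.year, b.capture_date.year + 1))
            intervals.append(
                GrowthInterval(
                    individual_id=ind_id,
                    site_id=a.site_id,
                    x_svl_mm=a.svl_mm,
                    z_mm=b.svl_mm - a.svl_mm,
                    t_days=(b.capture_date - a.capture_date).days,
                    years_spanned=years,
                    harvest_state=_harvest_state(site, a.capture_date, b.capture_date),
                )
            )
    return ModelData(intervals)


def compute_sample_mean_svl(intervals: Sequence[GrowthInterval]) -> float:
    """Arithmetic mean of interval start lengths (the model's E(X)), mm."""
    if not intervals:
        raise ValueError("no intervals: cannot compute mean start SVL")
    return float(np.mean([iv.x_svl_mm for iv in intervals]))
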