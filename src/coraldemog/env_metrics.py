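"""Thermal-stress climatologies and annual environmental summaries.

Daily series are pandas Series with a contiguous daily DatetimeIndex; the
Series ``name`` carries the site label. From daily SST the module computes a
maximum/minimum monthly-mean climatology (MMM/mMM) and three rolling
accumulation metrics in °C-weeks over a trailing 84-day (12-week) window that
includes the current day:

* ``DHW_0C``  — heat stress: positive exceedances of MMM, divided by 7. The 0 °C
  anomaly threshold accumulates low-level heat stress, so values exceed the
  conventional satellite product that only counts anomalies above MMM + 1 °C.
* ``DCW_0C``  — cold stress: deficits below mMM (stored negative).
* ``DCW_1C``  — cold stress with accumulation starting at mMM + 1 °C.

The first 83 days of each metric are reported missing (burn-in) rather than as
partial sums. Cold-stress series are kept negative internally ("larger negative
values mean more cold stress"); reporting layers emit the magnitude.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Climatology",
    "StressSeries",
    "compute_climatology",
    "compute_dhw",
    "compute_dcw",
    "build_stress_series",
    "gap_fill_linear",
    "annual_summaries",
    "read_daily_csv",
    "WINDOW_DAYS",
]

WINDOW_DAYS = 84  # 12 weeks, inclusive of the current day
_BURN_IN = WINDOW_DAYS - 1

_MONTH_NAMES = [calendar.month_name[m] for m in range(1, 13)]


@dataclass(frozen=True)
class Climatology:
    """Monthly-mean SST climatology with its hot and cold extremes.

    ``mmm`` is the maximum of the 12 climatological monthly means (MMM, the
    heat-stress baseline); ``mmm_min`` the minimum (mMM, the cold-stress
    baseline).
    """

    site: str
    monthly_means: np.ndarray  # 12 values, January..December, °C
    mmm: float
    mmm_min: float
    baseline: tuple[int, int]  # first and last year averaged

    def __post_init__(self) -> None:
        if len(self.monthly_means) != 12:
            raise ValueError("monthly_means must have 12 entries")
        if not (self.mmm_min <= self.mmm):
            raise ValueError("mMM must not exceed MMM")


@dataclass(frozen=True)
class StressSeries:
    """Daily rolling stress metrics for one site: dhw0 >= 0, dcw0/dcw1 <= 0."""

    site: str
    frame: pd.DataFrame  # columns dhw0, dcw0, dcw1, daily DatetimeIndex


def _validate_daily(series: pd.Series, allow_missing: bool = False) -> None:
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("daily series must be indexed by dates")
    diffs = series.index.to_series().diff().dropna()
    if len(series) > 1 and not (diffs == pd.Timedelta(days=1)).all():
        raise ValueError("dates must be strictly increasing with a daily step")
    if not allow_missing and series.isna().any():
        raise ValueError("SST series must contain no missing days")


def compute_climatology(
    sst: pd.Series,
    baseline_years: Sequence[int] | None = None,
    site: str | None = None,
) -> Climatology:
    """Average daily SST to monthly means per year, then across baseline years.

    Every calendar month must be represented in at least one baseline year.
    Leap days fall into February's mean. When ``baseline_years`` is omitted the
    full record is the baseline (a fixed satellite-era baseline can instead be
    supplied externally by constructing :class:`Climatology` directly).
    """
    _validate_daily(sst)
    site = site if site is not None else (sst.name or "")
    frame = sst.to_frame("sst")
    frame["year"] = frame.index.year
    frame["month"] = frame.index.month
    if baseline_years is not None:
        frame = frame[frame["year"].isin(list(baseline_years))]
        if frame.empty:
            raise ValueError("baseline years not present in the series")
    per_year_month = frame.groupby(["year", "month"])["sst"].mean()
    monthly = per_year_month.groupby("month").mean()
    missing = sorted(set(range(1, 13)) - set(monthly.index))
    if missing:
        names = ", ".join(_MONTH_NAMES[m - 1] for m in missing)
        raise ValueError(f"baseline does not cover calendar month(s): {names}")
    values = monthly.reindex(range(1, 13)).to_numpy(float)
    years = frame["year"].to_numpy()
    return Climatology(
        site=site,
        monthly_means=values,
        mmm=float(values.max()),
        mmm_min=float(values.min()),
        baseline=(int(years.min()), int(years.max())),
    )


def _check_site(series: pd.Series, clim: Climatology) -> None:
    if series.name and clim.site and series.name != clim.site:
        raise ValueError(
            f"series site {series.name!r} does not match climatology site {clim.site!r}"
        )


def _rolling_accumulation(daily_anomaly: pd.Series) -> pd.Series:
    out = daily_anomaly.rolling(WINDOW_DAYS, min_periods=WINDOW_DAYS).sum() / 7.0
    return out  # first 83 days NaN: burn-in


def compute_dhw(
    sst: pd.Series, clim: Climatology, anomaly_threshold: float = 0.0
) -> pd.Series:
    """Degree Heating Weeks: trailing 84-day sum of exceedances above
    MMM + ``anomaly_threshold``, divided by 7 (°C-weeks, >= 0)."""
    _validate_daily(sst)
    _check_site(sst, clim)
    if len(sst) < WINDOW_DAYS:
        raise ValueError(f"series must span at least {WINDOW_DAYS} days")
    exceed = (sst - (clim.mmm + anomaly_threshold)).clip(lower=0.0)
    out = _rolling_accumulation(exceed)
    out.name = sst.name
    return out


def compute_dcw(sst: pd.Series, clim: Climatology, offset: float = 0.0) -> pd.Series:
    """Degree Cooling Weeks: trailing 84-day accumulation of deficits below
    mMM + ``offset``, divided by 7 (°C-weeks, <= 0; magnitude is cold stress).

    ``offset=0`` gives DCW_0C; ``offset=1`` starts accumulating as soon as SST
    drops below mMM + 1 °C (DCW_1C), capturing very low-magnitude cold stress.
    """
    _validate_daily(sst)
    _check_site(sst, clim)
    if len(sst) < WINDOW_DAYS:
        raise ValueError(f"series must span at least {WINDOW_DAYS} days")
    deficit = (sst - (clim.mmm_min + offset)).clip(upper=0.0)
    out = _rolling_accumulation(deficit)
    out.name = sst.name
    return out


def build_stress_series(sst: pd.Series, clim: Climatology) -> StressSeries:
    """Compute dhw0, dcw0 and dcw1 together for one site."""
    frame = pd.DataFrame(
        {
            "dhw0": compute_dhw(sst, clim, anomaly_threshold=0.0),
            "dcw0": compute_dcw(sst, clim, offset=0.0),
            "dcw1": compute_dcw(sst, clim, offset=1.0),
        }
    )
    return StressSeries(site=str(sst.name or clim.site), frame=frame)


def gap_fill_linear(chla: pd.Series) -> pd.Series:
    """Linearly interpolate interior gaps in a daily series.

    Leading and trailing gaps are left missing — no extrapolation. Non-missing
    values are returned unchanged.
    """
    _validate_daily(chla, allow_missing=True)
    n_obs = int(chla.notna().sum())
    if n_obs == 0:
        raise ValueError("cannot gap-fill an all-missing series")
    if n_obs < 2:
        raise ValueError("need at least two observed values to interpolate")
    out = chla.interpolate(method="time", limit_area="inside")
    out.name = chla.name
    return out


def _complete_years(index: pd.DatetimeIndex) -> set[int]:
    counts = pd.Series(1, index=index).groupby(index.year).sum()
    return {
        int(y)
        for y, c in counts.items()
        if c == (366 if calendar.isleap(int(y)) else 365)
    }


def annual_summaries(
    sst: pd.Series,
    chla_filled: pd.Series,
    stress: StressSeries,
    include_partial_years: bool = False,
) -> pd.DataFrame:
    """Per-site-and-year means and within-year stress maxima.

    Returns a tidy frame with columns site, year, sst_mean, chla_mean,
    dhw0_max and dcw1_maxmag (cold stress reported as a positive magnitude).
    Partial calendar years are excluded by default, with a warning naming them;
    burn-in days of the rolling metrics are already missing and are skipped by
    the maxima.
    """
    _validate_daily(sst)
    years = sorted(set(sst.index.year))
    complete = _complete_years(sst.index)
    partial = [y for y in years if y not in complete]
    if partial and not include_partial_years:
        warnings.warn(f"excluding partial calendar year(s): {partial}")
        years = [y for y in years if y in complete]
    rows = []
    for year in years:
        sel = sst.index.year == year
        chla_year = chla_filled[chla_filled.index.year == year]
        sf = stress.frame[stress.frame.index.year == year]
        rows.append(
            {
                "site": str(sst.name or stress.site),
                "year": int(year),
                "sst_mean": float(sst[sel].mean()),
                "chla_mean": float(chla_year.mean()),
                "dhw0_max": float(sf["dhw0"].max()),
                "dcw1_maxmag": float(sf["dcw1"].min() * -1.0),
            }
        )
    return pd.DataFrame(rows)


def read_daily_csv(path, site: str | None = None) -> dict[str, pd.Series]:
    """Read long-format daily series CSV (site, date, value) into per-site Series."""
    frame = pd.read_csv(path, parse_dates=["date"])
    required = {"site", "date", "value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"daily CSV must have columns {sorted(required)}")
    out: dict[str, pd.Series] = {}
    for name, grp in frame.groupby("site"):
        if site is not None and name != site:
            continue
        s = grp.set_index("date")["value"].sort_index()
        s.name = name
        out[str(name)] = s
    return out
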