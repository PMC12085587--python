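"""Environmental composites for reef sites: annual/summer SST means, anomalies,
Degree Heating Weeks (DHW), thermal-stress event counts and five-year bins.

A daily environmental series is a :class:`pandas.DataFrame` with a ``date``
column (datetime64) and per-variable columns (``sst`` in °C, ``kd490`` in m⁻¹,
``chl`` in mg/m³, optionally ``rainfall`` in mm and ``wind`` in m/s).  Dates
must be strictly increasing; gaps are allowed and handled per operation
(means ignore them and report coverage, the DHW running sum is strict).

DHW follows the NOAA Coral Reef Watch accumulation rule: the daily *hotspot*
is ``max(SST − MMM, 0)`` where MMM is the maximum of the twelve monthly-mean
climatology values; only hotspots of at least 1 °C accumulate, summed over a
trailing 84-day (12-week) window and divided by 7 to give °C-weeks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteClimatology",
    "FIVE_YEAR_BINS",
    "SUMMER_MONTHS",
    "annual_mean",
    "summer_mean_sst",
    "sst_anomaly",
    "sst_climatology",
    "compute_dhw",
    "annual_max_dhw",
    "count_stress_events",
    "five_year_bin",
]

#: Climatologically warmest months at the study latitude (austral summer).
SUMMER_MONTHS = (1, 2, 3, 4)

#: Five-year analysis bins; the final bin spans four years by design.
FIVE_YEAR_BINS = ((1998, 2002), (2003, 2007), (2008, 2012), (2013, 2016))

#: DHW accumulation constants (Coral Reef Watch methodology).
DHW_WINDOW_DAYS = 84
DHW_HOTSPOT_THRESHOLD = 1.0


@dataclass(frozen=True)
class SiteClimatology:
    """Monthly SST climatology for one site over a reference period.

    ``mmm`` is the maximum of the twelve monthly means — the DHW baseline.
    """

    monthly_mean_sst: tuple  # 12 values, °C, Jan..Dec
    period: tuple            # (first_year, last_year) inclusive
    mmm: float = field(init=False)

    def __post_init__(self):
        if len(self.monthly_mean_sst) != 12:
            raise ValueError("monthly_mean_sst must have 12 entries")
        object.__setattr__(self, "monthly_mean_sst",
                           tuple(float(v) for v in self.monthly_mean_sst))
        object.__setattr__(self, "mmm", max(self.monthly_mean_sst))


def _check_dates(series: pd.DataFrame) -> pd.Series:
    dates = pd.to_datetime(series["date"])
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise ValueError("dates must be strictly increasing")
    return dates


def annual_mean(series: pd.DataFrame, variable: str,
                months: tuple | None = None) -> pd.DataFrame:
    """Arithmetic mean of daily values per calendar year.

    Missing days are ignored; ``coverage`` reports the fraction of calendar
    days (restricted to ``months`` if given) actually observed.  Years with no
    observations are absent, with a warning.
    """
    dates = _check_dates(series)
    df = pd.DataFrame({"date": dates, "value": series[variable].to_numpy(float)})
    df = df.dropna(subset=["value"])
    if months is not None:
        df = df[df["date"].dt.month.isin(months)]
    grouped = df.groupby(df["date"].dt.year)["value"]
    out = grouped.mean().rename("mean").to_frame()
    out["n_days"] = grouped.size()
    expected = []
    for year in out.index:
        cal = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        if months is not None:
            cal = cal[cal.month.isin(months)]
        expected.append(len(cal))
    out["coverage"] = out["n_days"] / np.asarray(expected, dtype=float)
    out.index.name = "year"
    all_years = range(int(dates.dt.year.min()), int(dates.dt.year.max()) + 1)
    missing = sorted(set(all_years) - set(out.index))
    if missing:
        warnings.warn(f"years without observations for {variable!r}: {missing}")
    return out.reset_index()


def summer_mean_sst(series: pd.DataFrame,
                    months: tuple = SUMMER_MONTHS) -> pd.DataFrame:
    """Per-year mean SST over the warmest months (January–April).

    Years missing one or more whole summer months are flagged in
    ``incomplete``.
    """
    out = annual_mean(series, "sst", months=months)
    dates = pd.to_datetime(series.loc[series["sst"].notna(), "date"])
    present = dates.groupby([dates.dt.year, dates.dt.month]).size()
    flags = []
    for year in out["year"]:
        have = {m for (y, m) in present.index if y == year}
        flags.append(not set(months).issubset(have))
    out["incomplete"] = flags
    return out


def sst_anomaly(means: pd.DataFrame, period: tuple = (1998, 2016)) -> pd.DataFrame:
    """Anomaly of annual (or summer) composite means versus their own
    climatological mean over ``period``.

    The mean anomaly over the climatology period is zero by construction.
    """
    years = means["year"].to_numpy()
    in_period = (years >= period[0]) & (years <= period[1])
    if not in_period.any():
        raise ValueError(f"series does not cover climatology period {period}")
    baseline = means.loc[in_period, "mean"].mean()
    out = means.copy()
    out["anomaly"] = out["mean"] - baseline
    return out


def sst_climatology(series: pd.DataFrame,
                    period: tuple = (1998, 2016)) -> SiteClimatology:
    """Monthly-mean SST climatology (and MMM) from a daily series."""
    dates = _check_dates(series)
    mask = (dates.dt.year >= period[0]) & (dates.dt.year <= period[1])
    if not mask.any():
        raise ValueError(f"series does not cover climatology period {period}")
    sst = series.loc[mask, "sst"].to_numpy(float)
    months = dates.dt.month.to_numpy()[mask.to_numpy()]
    monthly = [float(np.nanmean(sst[months == m])) for m in range(1, 13)]
    if any(np.isnan(monthly)):
        raise ValueError("climatology period does not cover all 12 months")
    return SiteClimatology(monthly_mean_sst=tuple(monthly), period=tuple(period))


def compute_dhw(series: pd.DataFrame, clim: SiteClimatology | None = None,
                mmm: float | None = None) -> pd.DataFrame:
    """Degree Heating Weeks from a daily SST series.

    Either a :class:`SiteClimatology` or an externally supplied ``mmm`` must be
    given.  The first 83 days carry no DHW value (the trailing window is not
    yet full), and any day whose 84-day window contains a gap is marked
    missing: DHW is a running sum, so a silent gap would understate stress.

    Returns columns ``date``, ``hotspot`` (°C) and ``dhw`` (°C-weeks).
    """
    if mmm is None:
        if clim is None:
            raise ValueError("provide a climatology or an explicit MMM")
        mmm = clim.mmm
    dates = _check_dates(series)
    if len(dates) < DHW_WINDOW_DAYS:
        raise ValueError(f"need at least {DHW_WINDOW_DAYS} days of SST for DHW")
    full = pd.DataFrame({"sst": series["sst"].to_numpy(float)},
                        index=pd.DatetimeIndex(dates))
    full = full.reindex(pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D"))
    hotspot = np.maximum(full["sst"] - mmm, 0.0)
    qualifying = hotspot.where(hotspot >= DHW_HOTSPOT_THRESHOLD, 0.0)
    # min_periods enforces the strict-gap policy: any NaN inside the window
    # (or a not-yet-full window) propagates to NaN via the sum over raw values.
    dhw = (qualifying.where(full["sst"].notna())
           .rolling(DHW_WINDOW_DAYS, min_periods=DHW_WINDOW_DAYS).sum() / 7.0)
    out = pd.DataFrame({"date": full.index, "hotspot": hotspot.to_numpy(),
                        "dhw": dhw.to_numpy()})
    return out[full["sst"].notna().to_numpy()].reset_index(drop=True)


def annual_max_dhw(ts: pd.DataFrame) -> pd.DataFrame:
    """Maximum DHW per calendar year (NaN if the year has no valid DHW)."""
    dates = pd.to_datetime(ts["date"])
    grouped = ts.groupby(dates.dt.year)["dhw"]
    out = grouped.max().rename("max_dhw").to_frame()
    out.index.name = "year"
    return out.reset_index()


def count_stress_events(ts: pd.DataFrame, threshold: float = 4.0,
                        bin_interval: tuple | None = None,
                        per_year: bool = False) -> int:
    """Number of thermal-stress events with DHW at or above ``threshold``.

    An event is a maximal contiguous run of days with ``dhw >= threshold``;
    a run is attributed to the interval containing its peak day, so events
    straddling a bin edge are counted once.  With ``per_year=True`` the count
    is instead the number of calendar years in the interval containing any
    exceedance (the alternative reading of an "event").
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dates = pd.to_datetime(ts["date"]).reset_index(drop=True)
    dhw = ts["dhw"].to_numpy(float)
    exceed = np.nan_to_num(dhw, nan=-np.inf) >= threshold
    if per_year:
        years = dates.dt.year.to_numpy()[exceed]
        if bin_interval is not None:
            years = years[(years >= bin_interval[0]) & (years <= bin_interval[1])]
        return int(len(np.unique(years)))
    count = 0
    i = 0
    n = len(exceed)
    while i < n:
        if exceed[i]:
            j = i
            while j + 1 < n and exceed[j + 1]:
                j += 1
            peak_day = dates[i + int(np.argmax(dhw[i:j + 1]))]
            if bin_interval is None or bin_interval[0] <= peak_day.year <= bin_interval[1]:
                count += 1
            i = j + 1
        else:
            i += 1
    return count


def five_year_bin(annual: pd.DataFrame, statistics: dict | None = None,
                  bins: tuple = FIVE_YEAR_BINS) -> pd.DataFrame:
    """Aggregate a per-year table into the study's five-year bins.

    ``statistics`` maps column name → "mean" | "max" | "sum" | "count"
    (default "mean"; use "max" for DHW maxima and "count" for events).  Years
    outside the binned range are rejected: silently dropping them would bias
    bin statistics.
    """
    years = annual["year"].to_numpy(int)
    lo, hi = bins[0][0], bins[-1][1]
    if years.min() < lo or years.max() > hi:
        raise ValueError(f"years outside binned range {lo}-{hi}")
    statistics = statistics or {}
    value_cols = [c for c in annual.columns if c != "year"]
    rows = []
    for b0, b1 in bins:
        sel = annual[(years >= b0) & (years <= b1)]
        row = {"bin": f"{b0}-{b1}", "n_years": len(sel)}
        for col in value_cols:
            stat = statistics.get(col, "mean")
            agg = getattr(sel[col], stat)
            row[col] = agg() if len(sel) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
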