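"""Hierarchical temporal averaging of hourly monitor data.

Hourly observations are reduced to daily, weekly (ISO-8601), annual, and
long-term mean (LTM) concentrations under completeness criteria: a day needs
at least 12 of its 24 hours, a week at least 3 of its 7 days, and a year at
least 25% of its ISO weeks (ceil(0.25 × weeks-in-year)). Values failing a
criterion are reported missing — no gap imputation. Days are delimited in
local standard time via a configurable UTC offset (default +8, an East-Asian
study domain).

All functions take and return tidy DataFrames. The aggregate schema is
``site_id, period, period_key, value, n_contributing`` where ``value`` is
NaN exactly when the completeness criterion failed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

MIN_HOURS_PER_DAY = 12
MIN_DAYS_PER_WEEK = 3
MIN_WEEK_FRACTION_PER_YEAR = 0.25


def _as_aggregate(
    grouped: pd.DataFrame, period: str, min_count: int | pd.Series
) -> pd.DataFrame:
    out = grouped.copy()
    out["period"] = period
    ok = out["n_contributing"] >= min_count
    out.loc[~ok, "value"] = np.nan
    return out[["site_id", "period", "period_key", "value", "n_contributing"]]


def daily_average(
    hourly: pd.DataFrame, utc_offset_hours: int = 8, min_hours: int = MIN_HOURS_PER_DAY
) -> pd.DataFrame:
    """Daily means of present hours; a day with fewer than ``min_hours``
    (default 12, i.e. 50% of 24) present hours is missing.

    ``hourly`` columns: site_id, timestamp (tz-aware or naive UTC), value.
    Duplicate (site, hour) rows raise.
    """
    h = hourly.copy()
    ts = pd.to_datetime(h["timestamp"], utc=True)
    if (ts != ts.dt.floor("h")).any():
        raise ValueError("timestamps must be hour-aligned")
    local = ts + pd.Timedelta(hours=utc_offset_hours)
    h["period_key"] = local.dt.strftime("%Y-%m-%d")
    if h.duplicated(subset=["site_id", "timestamp"]).any():
        dup = h[h.duplicated(subset=["site_id", "timestamp"], keep=False)]
        raise ValueError(
            f"duplicate site-hour rows, e.g. {dup.iloc[0]['site_id']} "
            f"{dup.iloc[0]['timestamp']}"
        )
    g = (
        h.groupby(["site_id", "period_key"], sort=True)["value"]
        .agg(value="mean", n_contributing="count")
        .reset_index()
    )
    return _as_aggregate(g, "day", min_hours)


def _iso_week_key(dates: pd.Series) -> pd.Series:
    iso = pd.to_datetime(dates).dt.isocalendar()
    return (
        iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
    ).set_axis(dates.index)


def weekly_average(
    daily: pd.DataFrame, min_days: int = MIN_DAYS_PER_WEEK
) -> pd.DataFrame:
    """ISO-week means of available daily values; weeks with fewer than
    ``min_days`` (default 3) available days are missing. A week belongs to
    its ISO year (the year of its Thursday)."""
    d = daily[daily["period"] == "day"].dropna(subset=["value"]).copy()
    d["period_key"] = _iso_week_key(d["period_key"])
    g = (
        d.groupby(["site_id", "period_key"], sort=True)["value"]
        .agg(value="mean", n_contributing="count")
        .reset_index()
    )
    return _as_aggregate(g, "week", min_days)


def _iso_weeks_in_year(year: int) -> int:
    # ISO years have 53 weeks iff Jan 1 or Dec 31 falls on a Thursday
    return pd.Timestamp(year=year, month=12, day=28).isocalendar().week


def annual_average(
    weekly: pd.DataFrame, min_week_fraction: float = MIN_WEEK_FRACTION_PER_YEAR
) -> pd.DataFrame:
    """Annual means of available weekly values; a year with fewer than
    ceil(min_week_fraction × weeks-in-ISO-year) available weeks is missing
    (default 25%: 13 of 52 weeks)."""
    w = weekly[weekly["period"] == "week"].dropna(subset=["value"]).copy()
    w["period_key"] = w["period_key"].str.split("-W").str[0]
    g = (
        w.groupby(["site_id", "period_key"], sort=True)["value"]
        .agg(value="mean", n_contributing="count")
        .reset_index()
    )
    need = g["period_key"].astype(int).map(
        lambda y: math.ceil(min_week_fraction * _iso_weeks_in_year(y))
    )
    return _as_aggregate(g, "year", need)


def long_term_mean(annual: pd.DataFrame, years: list[int]) -> pd.DataFrame:
    """Unweighted mean of each site's available annual averages over
    ``years``; sites with zero available years are missing."""
    if not years:
        raise ValueError("years must be a nonempty list")
    keys = {str(y) for y in years}
    a = annual[(annual["period"] == "year") & annual["period_key"].isin(keys)]
    avail = a.dropna(subset=["value"])
    g = (
        avail.groupby("site_id", sort=True)["value"]
        .agg(value="mean", n_contributing="count")
        .reset_index()
    )
    # sites present in the annual table but with no available year -> missing
    all_sites = pd.Index(a["site_id"].unique(), name="site_id")
    g = g.set_index("site_id").reindex(all_sites).reset_index()
    g["n_contributing"] = g["n_contributing"].fillna(0).astype(int)
    g["period_key"] = f"{min(years)}-{max(years)}"
    g["period"] = "LTM"
    return g[["site_id", "period", "period_key", "value", "n_contributing"]]


def aggregate_all(
    hourly: pd.DataFrame,
    years: list[int] | None = None,
    utc_offset_hours: int = 8,
) -> pd.DataFrame:
    """Run the full day → week → year → LTM cascade; returns the
    concatenated aggregate table."""
    daily = daily_average(hourly, utc_offset_hours=utc_offset_hours)
    weekly = weekly_average(daily)
    annual = annual_average(weekly)
    if years is None:
        years = sorted(annual["period_key"].astype(int).unique())
    ltm = long_term_mean(annual, years)
    return pd.concat([daily, weekly, annual, ltm], ignore_index=True)


def annual_wide(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Pivot annual + LTM rows to sites × periods of available values."""
    a = aggregates[aggregates["period"].isin(["year", "LTM"])]
    return a.pivot(index="site_id", columns="period_key", values="value")
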