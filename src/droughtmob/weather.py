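"""Corn-season weather aggregation and community-year classification.

Daily community weather (rainfall, maximum temperature) is aggregated
over state-specific corn-season windows into a season rainfall total and
the longest run of consecutive days with tmax above 30 degrees C.  Season
aggregates are standardized against the community's own 1980-1990
baseline; a community-year is *dry* (*wet*) when season rainfall falls at
least one baseline standard deviation below (above) the baseline mean,
and *hot* (*cool*) analogously for the heat-run statistic.  A boundary
value of exactly one standard deviation is classified into the extreme
category.  Neighbor exposure marks community-years whose adjacent
communities (an input adjacency table, e.g. communities within 50 km)
experienced dry conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HOT_DAY_THRESHOLD_C",
    "BASELINE_YEARS",
    "corn_season_window",
    "season_date_range",
    "aggregate_season",
    "aggregate_all_seasons",
    "max_hot_run",
    "BaselineStats",
    "baseline_stats",
    "classify",
    "classify_panel",
    "neighbor_dry",
    "add_neighbor_dry",
]

HOT_DAY_THRESHOLD_C = 30.0
BASELINE_YEARS = (1980, 1990)

#: state-specific corn-season month windows (start month, end month);
#: windows whose end month precedes the start month wrap the year
#: boundary and are indexed by their ending calendar year
_SEPT_MARCH_STATES = {"Baja California", "Chihuahua", "Nayarit", "Sinaloa", "Sonora"}

_MEXICAN_STATES = _SEPT_MARCH_STATES | {
    "Yucatan",
    "Aguascalientes", "Baja California Sur", "Campeche", "Chiapas", "Coahuila",
    "Colima", "Durango", "Guanajuato", "Guerrero", "Hidalgo", "Jalisco",
    "Mexico", "Michoacan", "Morelos", "Nuevo Leon", "Oaxaca", "Puebla",
    "Queretaro", "Quintana Roo", "San Luis Potosi", "Tabasco", "Tamaulipas",
    "Tlaxcala", "Veracruz", "Zacatecas", "Mexico City",
}


def corn_season_window(state_name: str) -> tuple[int, int]:
    """Corn-season month span for a Mexican state.

    June-February in Yucatan; September-March in Baja California,
    Chihuahua, Nayarit, Sinaloa and Sonora; May-December elsewhere.
    Months are 1-based; a window whose end month is smaller than its
    start month wraps the year boundary.
    """
    if state_name == "Yucatan":
        return (6, 2)
    if state_name in _SEPT_MARCH_STATES:
        return (9, 3)
    if state_name in _MEXICAN_STATES:
        return (5, 12)
    raise ValueError(f"unknown state {state_name!r}")


def season_date_range(window: tuple[int, int], harvest_year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """First and last calendar day of the season ending in ``harvest_year``."""
    start_month, end_month = window
    wraps = end_month < start_month
    start_year = harvest_year - 1 if wraps else harvest_year
    start = pd.Timestamp(year=start_year, month=start_month, day=1)
    end = pd.Timestamp(year=harvest_year, month=end_month, day=1) + pd.offsets.MonthEnd(0)
    return start, end


def max_hot_run(tmax: np.ndarray | list[float], threshold: float = HOT_DAY_THRESHOLD_C) -> int:
    """Longest run of consecutive days with tmax strictly above ``threshold``."""
    hot = np.asarray(tmax, dtype=float) > threshold
    if not hot.any():
        return 0
    # lengths of runs of True
    padded = np.concatenate(([0], hot.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return int((edges[1::2] - edges[::2]).max())


def aggregate_season(
    daily: pd.DataFrame,
    window: tuple[int, int],
    harvest_year: int,
    *,
    max_missing: int = 0,
) -> dict:
    """Season aggregate for one community and one harvest year.

    ``daily`` needs columns ``date`` (datetime-like), ``rainfall_mm`` and
    ``tmax_c``.  Raises if more than ``max_missing`` days of the window
    are absent from the data.
    """
    start, end = season_date_range(window, harvest_year)
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"])
    sel = d[(d["date"] >= start) & (d["date"] <= end)].sort_values("date")
    expected = (end - start).days + 1
    if len(sel) < expected - max_missing:
        raise ValueError(
            f"season {start.date()}..{end.date()} has {expected - len(sel)} missing days"
        )
    return {
        "harvest_year": harvest_year,
        "rainfall_total": float(sel["rainfall_mm"].sum()),
        "max_hot_run": max_hot_run(sel["tmax_c"].to_numpy()),
        "n_days": int(len(sel)),
    }


def aggregate_all_seasons(
    daily: pd.DataFrame,
    state_of_community: dict | pd.Series,
    years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Season aggregates for every community and harvest year covered.

    ``daily`` needs columns ``community_id``, ``date``, ``rainfall_mm``,
    ``tmax_c``; ``state_of_community`` maps community ids to state names.
    Years without full coverage at the edges of the data are dropped.
    """
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    rows = []
    for cid, grp in daily.groupby("community_id", sort=True):
        grp = grp.sort_values("date")
        dates = grp["date"].to_numpy()
        rain = grp["rainfall_mm"].to_numpy()
        tmax = grp["tmax_c"].to_numpy()
        window = corn_season_window(state_of_community[cid])
        lo = int(grp["date"].iloc[0].year)
        hi = int(grp["date"].iloc[-1].year)
        year_range = range(*(years if years else (lo, hi + 1)))
        for year in year_range:
            start, end = season_date_range(window, year)
            if start.to_datetime64() < dates[0] or end.to_datetime64() > dates[-1]:
                continue
            i0 = dates.searchsorted(start.to_datetime64())
            i1 = dates.searchsorted(end.to_datetime64(), side="right")
            expected = (end - start).days + 1
            if i1 - i0 != expected:
                raise ValueError(
                    f"community {cid!r} season ending {year} has "
                    f"{expected - (i1 - i0)} missing days"
                )
            rows.append(
                {
                    "community_id": cid,
                    "harvest_year": year,
                    "rainfall_total": float(rain[i0:i1].sum()),
                    "max_hot_run": max_hot_run(tmax[i0:i1]),
                    "n_days": int(i1 - i0),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BaselineStats:
    """1980-1990 baseline moments of one community's season statistics."""

    community_id: object
    rain_mean: float
    rain_sd: float
    hot_mean: float
    hot_sd: float


def baseline_stats(
    seasons: pd.DataFrame, baseline_years: tuple[int, int] = BASELINE_YEARS
) -> dict[object, BaselineStats]:
    """Per-community baseline means and SDs over the baseline seasons."""
    lo, hi = baseline_years
    base = seasons[(seasons["harvest_year"] >= lo) & (seasons["harvest_year"] <= hi)]
    out = {}
    for cid, grp in base.groupby("community_id"):
        out[cid] = BaselineStats(
            community_id=cid,
            rain_mean=float(grp["rainfall_total"].mean()),
            rain_sd=float(grp["rainfall_total"].std(ddof=1)),
            hot_mean=float(grp["max_hot_run"].mean()),
            hot_sd=float(grp["max_hot_run"].std(ddof=1)),
        )
    return out


def classify(aggregate: dict | pd.Series, baseline: BaselineStats) -> dict:
    """Dry/wet/normal and hot/cool/normal labels for one community-year.

    z-scores are taken against the community's 1980-1990 baseline; the
    extreme categories include the |z| = 1 boundary.  A zero (or missing)
    baseline SD is degenerate and raises rather than silently classifying.
    """
    if not baseline.rain_sd > 0 or not baseline.hot_sd > 0:
        raise ValueError(
            f"community {baseline.community_id!r} has a degenerate baseline SD"
        )
    z_precip = (aggregate["rainfall_total"] - baseline.rain_mean) / baseline.rain_sd
    z_temp = (aggregate["max_hot_run"] - baseline.hot_mean) / baseline.hot_sd
    precip = "dry" if z_precip <= -1 else ("wet" if z_precip >= 1 else "normal")
    temp = "cool" if z_temp <= -1 else ("hot" if z_temp >= 1 else "normal")
    return {
        "community_id": baseline.community_id,
        "year": int(aggregate["harvest_year"]),
        "z_precip": float(z_precip),
        "z_temp": float(z_temp),
        "precip_category": precip,
        "temp_category": temp,
    }


def classify_panel(
    seasons: pd.DataFrame, baselines: dict[object, BaselineStats] | None = None
) -> pd.DataFrame:
    """Weather categories for every community-year in ``seasons``."""
    if baselines is None:
        baselines = baseline_stats(seasons)
    rows = []
    for _, row in seasons.iterrows():
        cid = row["community_id"]
        if cid not in baselines:
            raise ValueError(f"no baseline for community {cid!r}")
        rows.append(classify(row, baselines[cid]))
    return pd.DataFrame(rows)


def neighbor_dry(
    community_id,
    categories_for_year: pd.DataFrame,
    adjacency: pd.DataFrame,
) -> bool:
    """True iff any adjacent community is dry in the given year.

    ``adjacency`` is an undirected pair table with columns
    ``community_id`` and ``neighbor_id``; a community with no rows has an
    empty neighbor set (vacuously not exposed).  The index community's
    own condition is irrelevant.
    """
    known = set(adjacency["community_id"]) | set(adjacency["neighbor_id"])
    if community_id not in known:
        raise ValueError(f"community {community_id!r} absent from adjacency table")
    nbrs = set(
        adjacency.loc[adjacency["community_id"] == community_id, "neighbor_id"]
    ) | set(adjacency.loc[adjacency["neighbor_id"] == community_id, "community_id"])
    dry = set(
        categories_for_year.loc[
            categories_for_year["precip_category"] == "dry", "community_id"
        ]
    )
    return bool(nbrs & dry)


def add_neighbor_dry(categories: pd.DataFrame, adjacency: pd.DataFrame) -> pd.DataFrame:
    """Append a ``neighbor_dry`` column to a category table."""
    out = categories.copy()
    nbrs: dict[object, set] = {}
    for a, b in adjacency[["community_id", "neighbor_id"]].itertuples(index=False):
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)
    dry_by_year: dict[int, set] = {
        int(year): set(grp.loc[grp["precip_category"] == "dry", "community_id"])
        for year, grp in out.groupby("year")
    }
    out["neighbor_dry"] = [
        bool(nbrs.get(cid, set()) & dry_by_year.get(int(year), set()))
        for cid, year in zip(out["community_id"], out["year"])
    ]
    return out
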