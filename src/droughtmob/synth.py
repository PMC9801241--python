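"""Synthetic input generators for both pipeline arms.

Every generator is a pure function of its spec and seed.  The weather
generator emulates daily gridded community weather: season rainfall
totals follow a per-community normal law spread over the corn-season
days by a Dirichlet-gamma split, and daily maximum temperature follows a
seasonal sinusoid with AR(1) noise so that multi-day heat runs arise
naturally.  The panel generator plants known coefficients in a linear
probability for first internal migration, with state-year shocks and
community-year shocks inducing realistic intra-cluster correlation, so
that estimator bias and confidence-interval coverage can be measured
against ground truth.  The calibration generator writes ABM strategy and
household tables satisfying the cost/reward orderings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from droughtmob.abm import KIND_ORDER, ModelParams, validate_strategy_specs
from droughtmob.weather import corn_season_window, season_date_range

__all__ = [
    "WeatherGenSpec",
    "PanelGenSpec",
    "CalibrationGenSpec",
    "gen_daily_weather",
    "gen_panel",
    "gen_calibration",
    "gen_index_series",
    "gen_adjacency",
    "default_states",
    "write_fixtures",
]

#: 22 Mexican states hosting the surveyed communities; the first six get
#: the non-default corn-season windows
_STATE_POOL = [
    "Yucatan", "Sinaloa", "Sonora", "Chihuahua", "Nayarit", "Baja California",
    "Oaxaca", "Jalisco", "Michoacan", "Guanajuato", "Zacatecas", "Puebla",
    "Guerrero", "Hidalgo", "Veracruz", "Chiapas", "Durango", "San Luis Potosi",
    "Queretaro", "Morelos", "Tlaxcala", "Aguascalientes",
]


def default_states(n_states: int = 22) -> list[str]:
    if n_states > len(_STATE_POOL):
        raise ValueError(f"at most {len(_STATE_POOL)} states available")
    return _STATE_POOL[:n_states]


@dataclass(frozen=True)
class WeatherGenSpec:
    """Spec for the daily community weather generator."""

    n_communities: int = 93
    n_states: int = 22
    years: tuple[int, int] = (1980, 2018)
    season_rain_mean: float = 600.0  # mm, community means drawn around this
    season_rain_mean_spread: float = 150.0
    season_rain_cv: float = 0.25  # sd of season total as fraction of its mean
    tmax_base_mean: float = 26.0  # deg C
    tmax_base_spread: float = 1.5
    tmax_amplitude: float = 6.0
    tmax_ar: float = 0.7
    tmax_noise_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.years
        if not (lo <= 1980 and hi >= 1990):
            raise ValueError("years must include the 1980-1990 baseline window")
        if self.season_rain_cv < 0:
            raise ValueError("season_rain_cv must be >= 0")


def gen_daily_weather(spec: WeatherGenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate daily weather and the community/state assignment.

    Returns ``(daily, communities)``: daily rows are
    (community_id, date, rainfall_mm, tmax_c); communities rows are
    (community_id, state).  Harvest years run from ``years[0]`` to
    ``years[1]``; seasons that wrap the year boundary begin in the prior
    calendar year, so the daily range starts mid-``years[0] - 1``.
    """
    rng = np.random.default_rng(spec.seed)
    states = default_states(spec.n_states)
    comm_states = [states[i % len(states)] for i in range(spec.n_communities)]
    communities = pd.DataFrame(
        {"community_id": np.arange(spec.n_communities), "state": comm_states}
    )

    y0, y1 = spec.years
    dates = pd.date_range(f"{y0 - 1}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    n_days = len(dates)
    frames = []
    for cid in range(spec.n_communities):
        state = comm_states[cid]
        window = corn_season_window(state)
        mean_total = spec.season_rain_mean + spec.season_rain_mean_spread * rng.normal()
        mean_total = max(mean_total, 100.0)
        sd_total = spec.season_rain_cv * mean_total

        rain = np.zeros(n_days)
        for year in range(y0 - 1, y1 + 1):
            start, end = season_date_range(window, year)
            if start < dates[0]:  # season not fully covered by the data
                continue
            i0 = dates.searchsorted(start)
            i1 = dates.searchsorted(end) + 1
            ndays = i1 - i0
            total = mean_total + sd_total * rng.normal()
            total = max(total, 0.0)
            if sd_total == 0:
                total = mean_total
            w = rng.gamma(0.7, 1.0, ndays)  # Dirichlet split: many dry days
            rain[i0:i1] = total * w / w.sum()

        base = spec.tmax_base_mean + spec.tmax_base_spread * rng.normal()
        seasonal = base + spec.tmax_amplitude * np.sin(
            2 * np.pi * (doy - 110) / 365.25
        )
        eps = rng.normal(0.0, spec.tmax_noise_sd, n_days)
        ar = np.empty(n_days)
        ar[0] = eps[0]
        phi = spec.tmax_ar
        for t in range(1, n_days):  # AR(1) recursion
            ar[t] = phi * ar[t - 1] + eps[t]
        tmax = seasonal + ar * math.sqrt(1 - phi**2)

        frames.append(
            pd.DataFrame(
                {
                    "community_id": cid,
                    "date": dates,
                    "rainfall_mm": rain,
                    "tmax_c": tmax,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), communities


def gen_adjacency(n_communities: int, seed: int = 0, avg_neighbors: float = 3.0) -> pd.DataFrame:
    """Random community adjacency pairs (stand-in for a distance rule).

    Emulates a "communities within 50 km" adjacency with an average of
    ``avg_neighbors`` neighbors per community.
    """
    rng = np.random.default_rng(seed)
    p = min(avg_neighbors / max(n_communities - 1, 1), 1.0)
    rows = []
    for i in range(n_communities):
        for j in range(i + 1, n_communities):
            if rng.random() < p:
                rows.append({"community_id": i, "neighbor_id": j})
    return pd.DataFrame(rows, columns=["community_id", "neighbor_id"])


@dataclass(frozen=True)
class PanelGenSpec:
    """Spec for the migration-panel generator with planted effects.

    Planted weather coefficients default to the magnitudes the baseline
    analysis operates on (per-person-year probabilities, i.e. basis-point
    scale); interactions are zero unless planted explicitly.
    """

    n_persons: int = 7500  # ~50,000 person-years after risk-set truncation
    years: tuple[int, int] = (1991, 2018)
    base_rate: float = 0.016
    beta_dry_t1: float = 0.0024
    beta_wet_t1: float = -0.0006
    beta_hot_t1: float = -0.0013
    beta_cool_t1: float = 0.0002
    beta_dry_t2: float = 0.0
    beta_neighbor_dry: float = 0.0
    beta_dry_x_no_irrigation: float = 0.0
    beta_dry_x_properties_medium: float = 0.0
    beta_dry_x_properties_high: float = 0.0
    #: individual/household/community control effects (kept small so
    #: probabilities stay inside [0, 1])
    beta_age: float = -0.0001
    beta_sex: float = 0.002
    beta_household_head: float = 0.003
    beta_education: float = 0.0004
    #: shocks are truncated at +/- 2.5 sd to keep probabilities in [0, 1]
    state_year_shock_sd: float = 0.0015
    community_year_shock_sd: float = 0.0015
    mean_obs_years: int = 10
    seed: int = 0


def gen_panel(
    spec: PanelGenSpec,
    categories: pd.DataFrame,
    communities: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a person-year first-migration panel with planted effects.

    ``categories`` must cover every community for years
    ``years[0] - 2 .. years[1]`` (lag construction); ``communities``
    gives the community-to-state map.  The linear probability is

        p = base + beta'w(t-1) + planted interactions + delta'x
            + state-year shock + community-year shock,

    thresholded to a Bernoulli outcome; rows after a person's first
    migration are removed.  Probabilities outside [0, 1] raise.  Note the
    returned table already carries the lagged weather dummies; it can be
    fed to ``fit_lpm`` directly or rebuilt through ``build_panel``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    y0, y1 = spec.years
    comm_ids = communities["community_id"].to_numpy()
    n_comm = len(comm_ids)
    state_of = dict(zip(communities["community_id"], communities["state"]))

    cats = categories.set_index(["community_id", "year"])
    needed = [(c, y) for c in comm_ids for y in range(y0 - 2, y1)]
    missing = [k for k in needed if k not in cats.index]
    if missing:
        raise ValueError(f"categories missing community-years, e.g. {missing[:5]}")

    # community-level structure
    irr_share = rng.uniform(0.0, 0.6, n_comm)
    no_irrigation = (irr_share < 0.10).astype(int)
    low_irrigation = (irr_share < 0.25).astype(int)
    share_men_ag = rng.uniform(0.45, 0.95, n_comm)
    share_us = rng.uniform(0.0, 0.4, n_comm)
    internal_prev = rng.choice(["low", "medium", "high"], n_comm, p=[0.4, 0.4, 0.2])

    # person-level structure
    pid = np.arange(spec.n_persons)
    pcomm = rng.integers(0, n_comm, spec.n_persons)
    entry = rng.integers(y0, y1 + 1, spec.n_persons)
    age0 = rng.integers(15, 51, spec.n_persons)
    # observation ends at the panel edge or age 65, whichever comes first
    span = np.minimum(
        1 + rng.geometric(1.0 / spec.mean_obs_years, spec.n_persons), y1 - entry + 1
    )
    span = np.minimum(span, 65 - age0 + 1)
    sex = rng.integers(0, 2, spec.n_persons)
    head = (rng.random(spec.n_persons) < 0.3).astype(int)
    educ = np.minimum(rng.poisson(6.0, spec.n_persons), 16)
    properties = rng.choice(["none", "medium", "high"], spec.n_persons, p=[0.5, 0.3, 0.2])
    ag_labor = rng.choice(["all", "some", "none"], spec.n_persons, p=[0.4, 0.4, 0.2])
    prior_int = (rng.random(spec.n_persons) < 0.3).astype(int)
    prior_us = (rng.random(spec.n_persons) < 0.2).astype(int)

    # expand to person-years
    reps = span
    person = np.repeat(pid, reps)
    year = np.concatenate([np.arange(e, e + s) for e, s in zip(entry, span)])
    offset = np.concatenate([np.arange(s) for s in span])
    comm = np.repeat(pcomm, reps)

    cat_cols = cats[["precip_category", "temp_category"]]
    has_nbr = "neighbor_dry" in categories.columns

    def lag_lookup(col: str, lag: int) -> np.ndarray:
        key = pd.MultiIndex.from_arrays([comm, year - lag])
        return cats[col].reindex(key).to_numpy()

    dry_t1 = (lag_lookup("precip_category", 1) == "dry").astype(float)
    wet_t1 = (lag_lookup("precip_category", 1) == "wet").astype(float)
    hot_t1 = (lag_lookup("temp_category", 1) == "hot").astype(float)
    cool_t1 = (lag_lookup("temp_category", 1) == "cool").astype(float)
    dry_t2 = (lag_lookup("precip_category", 2) == "dry").astype(float)
    nbr_t1 = (
        lag_lookup("neighbor_dry", 1).astype(float) if has_nbr else np.zeros(len(person))
    )

    age = np.repeat(age0, reps) + offset
    props = np.repeat(properties, reps)
    no_irr = no_irrigation[comm]

    # state-year and community-year shocks
    states = np.array([state_of[c] for c in comm_ids])
    state_idx = pd.factorize(states)[0]
    n_states = state_idx.max() + 1
    years_all = np.arange(y0, y1 + 1)
    sy_shock = rng.normal(0.0, spec.state_year_shock_sd, (n_states, len(years_all)))
    cy_shock = rng.normal(0.0, spec.community_year_shock_sd, (n_comm, len(years_all)))
    sy_shock = np.clip(sy_shock, -2.5 * spec.state_year_shock_sd, 2.5 * spec.state_year_shock_sd)
    cy_shock = np.clip(cy_shock, -2.5 * spec.community_year_shock_sd, 2.5 * spec.community_year_shock_sd)
    yidx = year - y0

    p = (
        spec.base_rate
        + spec.beta_dry_t1 * dry_t1
        + spec.beta_wet_t1 * wet_t1
        + spec.beta_hot_t1 * hot_t1
        + spec.beta_cool_t1 * cool_t1
        + spec.beta_dry_t2 * dry_t2
        + spec.beta_neighbor_dry * nbr_t1
        + spec.beta_dry_x_no_irrigation * dry_t1 * no_irr
        + spec.beta_dry_x_properties_medium * dry_t1 * (props == "medium")
        + spec.beta_dry_x_properties_high * dry_t1 * (props == "high")
        + spec.beta_age * (age - 35)
        + spec.beta_sex * np.repeat(sex, reps)
        + spec.beta_household_head * np.repeat(head, reps)
        + spec.beta_education * (np.repeat(educ, reps) - 6)
        + sy_shock[state_idx[comm], yidx]
        + cy_shock[comm, yidx]
    )
    if (p < 0).any() or (p > 1).any():
        raise ValueError(
            f"implied probabilities outside [0, 1]: range "
            f"[{p.min():.4f}, {p.max():.4f}]"
        )
    y_out = (rng.random(len(p)) < p).astype(int)

    df = pd.DataFrame(
        {
            "person_id": person,
            "household_id": person,  # one household per person history
            "community_id": comm,
            "state_id": state_idx[comm],
            "year": year,
            "migrated": y_out,
            "age": age,
            "sex": np.repeat(sex, reps),
            "household_head": np.repeat(head, reps),
            "education": np.repeat(educ, reps),
            "properties": props,
            "ag_labor": np.repeat(ag_labor, reps),
            "prior_internal_migrants": np.repeat(prior_int, reps),
            "prior_us_migrants": np.repeat(prior_us, reps),
            "share_men_agriculture": share_men_ag[comm],
            "internal_prevalence": internal_prev[comm],
            "share_us_migration": share_us[comm],
            "no_irrigation": no_irr,
            "low_irrigation": low_irrigation[comm],
            "dry_t1": dry_t1,
            "wet_t1": wet_t1,
            "hot_t1": hot_t1,
            "cool_t1": cool_t1,
            "dry_t2": dry_t2,
            "neighbor_dry_t1": nbr_t1,
        }
    )
    # risk set: drop person-years after the first migration
    df = df.sort_values(["person_id", "year"])
    prior = df.groupby("person_id")["migrated"].transform(
        lambda s: s.shift(fill_value=0).cumsum()
    )
    return df[prior == 0].reset_index(drop=True)


@dataclass(frozen=True)
class CalibrationGenSpec:
    """Spec for the ABM calibration tables."""

    n_households: int = 100
    params: ModelParams = field(default_factory=ModelParams)
    wealth_jitter: float = 0.0  # extra lognormal sigma on top of params
    seed: int = 0


def gen_calibration(spec: CalibrationGenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``strategies`` and ``households`` calibration tables.

    Strategy rows satisfy the cost/reward orderings (validated); the
    household table draws starting wealth and risk aversion from the
    model's distributions.
    """
    validate_strategy_specs(spec.params.strategy_specs)
    rng = np.random.default_rng(spec.seed)
    strategies = pd.DataFrame(
        [
            {
                "kind": k.value,
                "upfront_cost": s.upfront_cost,
                "income_mean": s.income_mean,
                "income_sd": s.income_sd,
                "recurring": int(s.recurring),
            }
            for k, s in ((k, spec.params.strategy_specs[k]) for k in KIND_ORDER)
        ]
    )
    from droughtmob.simulation import _draw

    wealth = _draw(spec.params.wealth_distribution, spec.n_households, rng)
    r = _draw(spec.params.risk_aversion_distribution, spec.n_households, rng)
    households = pd.DataFrame(
        {
            "household_id": np.arange(spec.n_households),
            "wealth": wealth,
            "risk_aversion": r,
        }
    )
    return strategies, households


def gen_index_series(
    n_years: int, seed: int = 0, start_year: int = 1981
) -> pd.DataFrame:
    """Standardized drought-index series (i.i.d. standard normal)."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "year": np.arange(start_year, start_year + n_years),
            "value": rng.standard_normal(n_years),
        }
    )


def write_fixtures(outdir, seed: int = 0) -> dict[str, str]:
    """Write the miniature test dataset as delimited text files.

    Five communities in three states, 200 persons, 1986-2000 weather:
    small enough for test suites, rich enough to exercise every pipeline
    stage (the 1980-1990 baseline is included).
    """
    from pathlib import Path

    from droughtmob.weather import add_neighbor_dry, aggregate_all_seasons, classify_panel

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    wspec = WeatherGenSpec(n_communities=5, n_states=3, years=(1980, 2000), seed=seed)
    daily, communities = gen_daily_weather(wspec)
    seasons = aggregate_all_seasons(
        daily, dict(zip(communities["community_id"], communities["state"]))
    )
    adjacency = gen_adjacency(5, seed=seed, avg_neighbors=2.0)
    cats = add_neighbor_dry(classify_panel(seasons), adjacency)
    pspec = PanelGenSpec(n_persons=200, years=(1991, 2000), seed=seed)
    panel = gen_panel(pspec, cats, communities)
    strategies, households = gen_calibration(
        CalibrationGenSpec(n_households=20, seed=seed)
    )
    index = gen_index_series(40, seed=seed)

    paths = {}
    for name, df in [
        ("communities", communities),
        ("seasons", seasons),
        ("weather_categories", cats),
        ("adjacency", adjacency),
        ("panel", panel),
        ("strategies", strategies),
        ("households", households),
        ("drought_index", index),
    ]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths
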