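"""Per-cycle climate paths and crop-yield response.

The simulation runs on cropping cycles, two per calendar year, cycle 0
being the first cycle of 2007.  A climate path assigns each cycle a
temperature anomaly (degrees C above the 2007 baseline) and a drought
flag.  Droughts arrive stochastically with a 1-in-20-year probability
during 2007-2020; from then on only the scenario's forced drought cycles
occur.  A drought eliminates farming incomes in the cycles in which it
occurs; warming reduces mean crop yields linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "START_YEAR",
    "END_YEAR",
    "CYCLES_PER_YEAR",
    "n_cycles",
    "cycle_of",
    "year_of_cycle",
    "TrendSpec",
    "DroughtSpec",
    "ClimatePath",
    "make_climate_path",
    "yield_factor",
    "drought_probability_from_index",
    "read_index_series",
]

START_YEAR = 2007
END_YEAR = 2035
CYCLES_PER_YEAR = 2


def n_cycles(start_year: int = START_YEAR, end_year: int = END_YEAR) -> int:
    return CYCLES_PER_YEAR * (end_year - start_year + 1)


def cycle_of(year: int, half: int = 0, start_year: int = START_YEAR) -> int:
    """Index of the given cropping cycle (half in {0, 1}) of ``year``."""
    if half not in (0, 1):
        raise ValueError("half must be 0 or 1")
    return CYCLES_PER_YEAR * (year - start_year) + half


def year_of_cycle(cycle: int, start_year: int = START_YEAR) -> int:
    return start_year + cycle // CYCLES_PER_YEAR


def year_cycles(year: int, start_year: int = START_YEAR) -> tuple[int, int]:
    """Both cycle indices of a calendar year."""
    c = cycle_of(year, 0, start_year)
    return (c, c + 1)


@dataclass(frozen=True)
class TrendSpec:
    """Long-term temperature trend.

    kind:
      * ``"stationary"`` -- anomaly 0 throughout;
      * ``"gradual_to_year"`` -- linear ramp from 0 in the start year to
        ``delta_t`` degrees in ``year`` (which may lie beyond the horizon);
      * ``"spike_year"`` -- anomaly ``delta_t`` in the named year only.
    """

    kind: str = "stationary"
    delta_t: float = 0.0
    year: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("stationary", "gradual_to_year", "spike_year"):
            raise ValueError(f"unknown trend kind {self.kind!r}")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")
        if self.kind != "stationary" and self.year is None:
            raise ValueError(f"trend kind {self.kind!r} requires a year")

    def anomaly(self, year: int, start_year: int = START_YEAR) -> float:
        if self.kind == "stationary":
            return 0.0
        if self.kind == "gradual_to_year":
            span = self.year - start_year
            if span <= 0:
                return self.delta_t
            return self.delta_t * (year - start_year) / span
        return self.delta_t if year == self.year else 0.0


@dataclass(frozen=True)
class DroughtSpec:
    """Stochastic plus forced drought forcing.

    Stochastic droughts occur per calendar year with
    ``stochastic_annual_probability`` over ``stochastic_years``
    (inclusive); a drought year flags both of that year's cycles.
    ``forced_cycles`` are flagged deterministically.
    """

    stochastic_annual_probability: float = 1.0 / 20.0
    stochastic_years: tuple[int, int] = (2007, 2020)
    forced_cycles: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0 <= self.stochastic_annual_probability <= 1:
            raise ValueError("stochastic_annual_probability must lie in [0, 1]")


@dataclass(frozen=True)
class ClimatePath:
    """Realised per-cycle forcing over the simulation horizon."""

    temp_anomaly: np.ndarray
    drought_flag: np.ndarray
    start_year: int = START_YEAR

    def __post_init__(self) -> None:
        if len(self.temp_anomaly) != len(self.drought_flag):
            raise ValueError("anomaly and drought arrays must have equal length")
        if not np.all(np.isfinite(self.temp_anomaly)):
            raise ValueError("temperature anomalies must be finite")

    def __len__(self) -> int:
        return len(self.temp_anomaly)


def make_climate_path(
    trend: TrendSpec,
    drought: DroughtSpec,
    horizon: tuple[int, int] = (START_YEAR, END_YEAR),
    rng: np.random.Generator | int | None = None,
) -> ClimatePath:
    """Realise one climate path over ``horizon`` (inclusive years).

    Both cycles of a calendar year share that year's trend anomaly.
    Stochastic droughts are drawn per year within the spec's active
    window; forced cycles are always flagged and must lie inside the
    horizon.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    start, end = horizon
    total = n_cycles(start, end)
    if drought.forced_cycles and (
        min(drought.forced_cycles) < 0 or max(drought.forced_cycles) >= total
    ):
        raise ValueError(
            f"forced cycles {sorted(drought.forced_cycles)} outside horizon of {total} cycles"
        )
    anomaly = np.empty(total)
    flags = np.zeros(total, dtype=bool)
    for year in range(start, end + 1):
        a = trend.anomaly(year, start)
        c0, c1 = year_cycles(year, start)
        anomaly[c0] = anomaly[c1] = a
        lo, hi = drought.stochastic_years
        if lo <= year <= hi and rng.random() < drought.stochastic_annual_probability:
            flags[c0] = flags[c1] = True
    for c in drought.forced_cycles:
        flags[c] = True
    return ClimatePath(anomaly, flags, start_year=start)


def yield_factor(temp_anomaly: float, drought_flag: bool, k: float = 0.07) -> float:
    """Crop-yield multiplier in [0, 1].

    A drought eliminates farming income (factor 0); otherwise yields
    decline linearly with warming at rate ``k`` per degree C, truncated
    to [0, 1].
    """
    if temp_anomaly < 0:
        raise ValueError("temp_anomaly must be >= 0")
    if drought_flag:
        return 0.0
    return float(np.clip(1.0 - k * temp_anomaly, 0.0, 1.0))


def drought_probability_from_index(
    index_series: np.ndarray | list[float], threshold: float = -1.5
) -> float:
    """Annual drought probability from a standardized drought-index series.

    The probability is the fraction of years whose index value is at or
    below ``threshold`` (a common severity cutoff for standardized
    indices such as the SPEI).
    """
    arr = np.asarray(index_series, dtype=float)
    if arr.size == 0:
        raise ValueError("index series is empty")
    return float(np.mean(arr <= threshold))


def read_index_series(path) -> np.ndarray:
    """Read a two-column (year, value) delimited text drought-index series."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: year, value")
    return df.iloc[:, 1].to_numpy(dtype=float)
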