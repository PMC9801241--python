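"""Experimental scenarios and ensemble statistics.

Eight scenarios cross a long-term climate trend, a social-network
topology, a community-wide information level, and a forced drought
pattern.  Ensembles of seeded runs record, per cropping cycle, the
proportion of households whose portfolio includes each strategy; the
headline outcome is the pre/post drought change in local and overseas
migration engagement, in percentage points, and its difference from the
base case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from droughtmob.abm import ModelParams, StrategyKind, build_network
from droughtmob.climate import (
    DroughtSpec,
    TrendSpec,
    cycle_of,
    make_climate_path,
    n_cycles,
)
from droughtmob.simulation import run_simulation

__all__ = [
    "Scenario",
    "SCENARIOS",
    "EnsembleResult",
    "DeltaSummary",
    "run_ensemble",
    "migration_delta",
    "delta_vs_base",
    "paired_delta_test",
]


@dataclass(frozen=True)
class Scenario:
    """One experimental condition."""

    name: str
    trend: TrendSpec
    topology: tuple[str, float]
    info_access: str
    drought: DroughtSpec

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "trend": {
                "kind": self.trend.kind,
                "delta_t": self.trend.delta_t,
                "year": self.trend.year,
            },
            "topology": {"kind": self.topology[0], "degree": self.topology[1]},
            "info_access": self.info_access,
            "drought": {
                "stochastic_annual_probability": self.drought.stochastic_annual_probability,
                "stochastic_years": list(self.drought.stochastic_years),
                "forced_cycles": sorted(self.drought.forced_cycles),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            name=d["name"],
            trend=TrendSpec(
                kind=d["trend"]["kind"],
                delta_t=d["trend"]["delta_t"],
                year=d["trend"]["year"],
            ),
            topology=(d["topology"]["kind"], d["topology"]["degree"]),
            info_access=d["info_access"],
            drought=DroughtSpec(
                stochastic_annual_probability=d["drought"]["stochastic_annual_probability"],
                stochastic_years=tuple(d["drought"]["stochastic_years"]),
                forced_cycles=frozenset(d["drought"]["forced_cycles"]),
            ),
        )


_SF = ("scale_free", 4.5)
_DROUGHT_2025 = frozenset({cycle_of(2025, 0), cycle_of(2025, 1)})
_DROUGHT_2024_25 = frozenset(
    {cycle_of(2024, 0), cycle_of(2024, 1), cycle_of(2025, 0), cycle_of(2025, 1)}
)
_GRADUAL = TrendSpec("gradual_to_year", 1.5, 2050)

#: The eight experimental scenarios.
SCENARIOS: dict[str, Scenario] = {
    "base_case": Scenario(
        "base_case", TrendSpec("stationary"), _SF, "partial", DroughtSpec()
    ),
    "single_drought": Scenario(
        "single_drought",
        TrendSpec("stationary"),
        _SF,
        "partial",
        DroughtSpec(forced_cycles=_DROUGHT_2025),
    ),
    "consecutive_droughts": Scenario(
        "consecutive_droughts",
        TrendSpec("stationary"),
        _SF,
        "partial",
        DroughtSpec(forced_cycles=_DROUGHT_2024_25),
    ),
    "drought_temp_spike": Scenario(
        "drought_temp_spike",
        TrendSpec("spike_year", 1.5, 2024),
        _SF,
        "partial",
        DroughtSpec(forced_cycles=_DROUGHT_2025),
    ),
    "drought_no_info": Scenario(
        "drought_no_info",
        _GRADUAL,
        _SF,
        "none",
        DroughtSpec(forced_cycles=_DROUGHT_2025),
    ),
    "drought_full_info": Scenario(
        "drought_full_info",
        _GRADUAL,
        _SF,
        "full",
        DroughtSpec(forced_cycles=_DROUGHT_2025),
    ),
    "drought_social_isolation": Scenario(
        "drought_social_isolation",
        _GRADUAL,
        ("uniform", 1),
        "partial",
        DroughtSpec(forced_cycles=_DROUGHT_2025),
    ),
    "drought_full_network": Scenario(
        "drought_full_network",
        _GRADUAL,
        ("uniform", 99),
        "partial",
        DroughtSpec(forced_cycles=_DROUGHT_2025),
    ),
}

#: comparison window used for the base case, which has no forced droughts
#: of its own: the single-drought cycles (both cycles of 2025).
DEFAULT_WINDOW_CYCLES = _DROUGHT_2025


@dataclass
class EnsembleResult:
    """Stacked per-run outcomes of one scenario."""

    scenario: Scenario
    proportions: np.ndarray  # (n_sims, n_cycles, 4)
    base_seed: int

    @property
    def n_sims(self) -> int:
        return self.proportions.shape[0]


@dataclass(frozen=True)
class DeltaSummary:
    """Ensemble summary of a pre/post migration change, in percentage points."""

    kind: StrategyKind
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int
    window: tuple[tuple[int, ...], tuple[int, ...]]  # (pre cycles, post cycles)


def run_ensemble(
    scenario: Scenario,
    n_sims: int = 1000,
    base_seed: int = 0,
    params: ModelParams | None = None,
) -> EnsembleResult:
    """Run ``n_sims`` independent seeded simulations of one scenario.

    Run ``i`` uses seed ``base_seed + i`` for the network draw, the
    climate path and the agent draws, so ensembles of different scenarios
    run with the same ``base_seed`` are seed-paired.
    """
    params = params or ModelParams()
    total = n_cycles()
    props = np.empty((n_sims, total, 4))
    for i in range(n_sims):
        seed = int(base_seed) + i
        graph = build_network(params.n_households, scenario.topology, seed)
        rng = np.random.default_rng(seed)
        path = make_climate_path(scenario.trend, scenario.drought, rng=rng)
        res = run_simulation(params, graph, scenario.info_access, path, seed)
        props[i] = res.proportions
    return EnsembleResult(scenario=scenario, proportions=props, base_seed=int(base_seed))


def delta_window(drought_cycles: frozenset[int] | set[int]) -> tuple[tuple[int, int], tuple[int, int]]:
    """Pre/post comparison cycles around a forced drought window.

    Pre = the two cycles immediately preceding the first drought cycle;
    post = the two cycles immediately following the last.
    """
    if not drought_cycles:
        raise ValueError("drought_cycles must be non-empty")
    first, last = min(drought_cycles), max(drought_cycles)
    pre = (first - 2, first - 1)
    post = (last + 1, last + 2)
    return pre, post


def per_run_deltas(
    ensemble: EnsembleResult, drought_cycles: frozenset[int] | set[int]
) -> dict[StrategyKind, np.ndarray]:
    """Per-run pre/post change for each strategy kind, in percentage points."""
    pre, post = delta_window(drought_cycles)
    total = ensemble.proportions.shape[1]
    if min(pre) < 0 or max(post) >= total:
        raise ValueError(f"comparison window {pre}+{post} outside horizon of {total} cycles")
    from droughtmob.abm import KIND_ORDER

    out = {}
    pre_mean = ensemble.proportions[:, list(pre), :].mean(axis=1)
    post_mean = ensemble.proportions[:, list(post), :].mean(axis=1)
    deltas = 100.0 * (post_mean - pre_mean)  # percentage points
    for j, k in enumerate(KIND_ORDER):
        out[k] = deltas[:, j]
    return out


def migration_delta(
    ensemble: EnsembleResult,
    drought_cycles: frozenset[int] | set[int] | None = None,
) -> dict[StrategyKind, DeltaSummary]:
    """Pre/post migration change summaries over an ensemble.

    ``drought_cycles`` defaults to the scenario's own forced cycles, or
    to the single-drought window for the (drought-free) base case so that
    conditions can be compared over the same calendar cycles.
    """
    if drought_cycles is None:
        drought_cycles = ensemble.scenario.drought.forced_cycles or DEFAULT_WINDOW_CYCLES
    deltas = per_run_deltas(ensemble, drought_cycles)
    pre, post = delta_window(drought_cycles)
    out = {}
    for k, d in deltas.items():
        n = len(d)
        mean = float(d.mean())
        if n > 1:
            sd = float(d.std(ddof=1))
            half = 1.96 * sd / np.sqrt(n)
            ci = (mean - half, mean + half)
        else:
            sd = float("nan")
            ci = (mean, mean)
        out[k] = DeltaSummary(
            kind=k, mean=mean, sd=sd, ci_low=ci[0], ci_high=ci[1], n=n,
            window=(pre, post),
        )
    return out


def delta_vs_base(condition: DeltaSummary, base: DeltaSummary) -> DeltaSummary:
    """Net change of a condition relative to the base case, with 95% CI.

    Both summaries must cover the same calendar window; the CI combines
    the two independent ensemble variances.
    """
    if condition.window != base.window:
        raise ValueError(
            f"mismatched comparison windows: {condition.window} vs {base.window}"
        )
    if condition.kind != base.kind:
        raise ValueError("summaries refer to different strategy kinds")
    diff = condition.mean - base.mean
    se = float(np.sqrt(condition.sd**2 / condition.n + base.sd**2 / base.n))
    return DeltaSummary(
        kind=condition.kind,
        mean=diff,
        sd=se,
        ci_low=diff - 1.96 * se,
        ci_high=diff + 1.96 * se,
        n=min(condition.n, base.n),
        window=condition.window,
    )


def paired_delta_test(
    cond_deltas: np.ndarray,
    base_deltas: np.ndarray,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Paired t-test of seed-matched per-run deltas.

    Returns ``(mean difference, one-sided p-value)`` for the alternative
    that the condition's delta exceeds (``"greater"``) or falls below
    (``"less"``) the comparison ensemble's delta.
    """
    if len(cond_deltas) != len(base_deltas):
        raise ValueError("paired test requires equal-length, seed-matched ensembles")
    diff = np.asarray(cond_deltas) - np.asarray(base_deltas)
    t = stats.ttest_1samp(diff, 0.0, alternative=alternative)
    return float(diff.mean()), float(t.pvalue)
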