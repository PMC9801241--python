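"""Agent-based model of household livelihood and migration choice.

Households in a single farming community each hold a *portfolio* of
livelihood strategies: exactly one farming strategy (low-risk subsistence
cereals or high-risk cash crops) plus optionally one or both migration
strategies (low-cost/low-reward local migration, high-cost/high-reward
overseas migration).  Under imperfect information, households form
perceptions of each strategy's income distribution from their social
network and a noisy government signal.  Each cropping cycle (two per
calendar year) a household keeps its status quo unless dissatisfied with
recent income relative to its neighbors and its own aspiration, in which
case it re-optimises a mean--variance objective

    U(p) = mu_p - r * sigma_p

over the feasible portfolios, where ``mu_p`` is the summed perceived mean
income of the portfolio (net of recurring input costs), ``sigma_p`` the
portfolio standard deviation under independent strategy incomes, and ``r``
the household's risk-aversion parameter.  Migration strategies carry a
one-time entry cost that falls with the share of a household's neighbors
already engaged in that strategy (migrant-network feedback), bounded below
by a cost floor.

This module holds the domain types and the per-household operations; the
vectorised community simulation lives in :mod:`droughtmob.simulation`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "StrategyKind",
    "FARMING_KINDS",
    "MIGRATION_KINDS",
    "KIND_ORDER",
    "StrategySpec",
    "HouseholdState",
    "ModelParams",
    "default_strategy_specs",
    "canonical_portfolios",
    "build_network",
    "perceive",
    "portfolio_utility",
    "feasible_portfolios",
    "portfolio_cost",
    "decide",
    "is_satisfied",
    "migration_cost",
]


class StrategyKind(str, enum.Enum):
    """The four livelihood strategies available to a household."""

    SUBSISTENCE_CROP = "subsistence_crop"
    CASH_CROP = "cash_crop"
    LOCAL_MIGRATION = "local_migration"
    OVERSEAS_MIGRATION = "overseas_migration"

    @property
    def is_farming(self) -> bool:
        return self in FARMING_KINDS

    @property
    def is_migration(self) -> bool:
        return self in MIGRATION_KINDS


FARMING_KINDS = (StrategyKind.SUBSISTENCE_CROP, StrategyKind.CASH_CROP)
MIGRATION_KINDS = (StrategyKind.LOCAL_MIGRATION, StrategyKind.OVERSEAS_MIGRATION)
#: canonical tie-break order: subsistence < cash < local < overseas
KIND_ORDER = FARMING_KINDS + MIGRATION_KINDS


@dataclass(frozen=True)
class StrategySpec:
    """Cost and income distribution of one livelihood strategy.

    ``upfront_cost`` is a per-cycle input cost for farming strategies
    (``recurring=True``) and a one-time entry cost for migration
    strategies (``recurring=False``), paid when the strategy is added to
    the portfolio.  Incomes are in community currency units per cropping
    cycle.
    """

    kind: StrategyKind
    upfront_cost: float
    income_mean: float
    income_sd: float
    recurring: bool

    def __post_init__(self) -> None:
        if self.upfront_cost < 0:
            raise ValueError("upfront_cost must be >= 0")
        if self.income_sd < 0:
            raise ValueError("income_sd must be >= 0")


def default_strategy_specs() -> dict[StrategyKind, StrategySpec]:
    """Default calibration of the four strategies.

    Orderings enforced: overseas migration costs more and rewards more
    than local migration; cash crops are riskier and higher-reward than
    subsistence cereals.  See docs/methods.md for the calibration
    rationale.
    """
    return {
        StrategyKind.SUBSISTENCE_CROP: StrategySpec(
            StrategyKind.SUBSISTENCE_CROP, 0.0, 10.0, 3.0, recurring=True
        ),
        StrategyKind.CASH_CROP: StrategySpec(
            StrategyKind.CASH_CROP, 3.0, 14.5, 5.0, recurring=True
        ),
        StrategyKind.LOCAL_MIGRATION: StrategySpec(
            StrategyKind.LOCAL_MIGRATION, 12.0, 1.0, 4.0, recurring=False
        ),
        StrategyKind.OVERSEAS_MIGRATION: StrategySpec(
            StrategyKind.OVERSEAS_MIGRATION, 100.0, 2.5, 9.0, recurring=False
        ),
    }


def validate_strategy_specs(specs: Mapping[StrategyKind, StrategySpec]) -> None:
    """Check the cross-strategy orderings of the calibration."""
    missing = [k for k in StrategyKind if k not in specs]
    if missing:
        raise ValueError(f"missing strategy specs: {missing}")
    local = specs[StrategyKind.LOCAL_MIGRATION]
    overseas = specs[StrategyKind.OVERSEAS_MIGRATION]
    if not overseas.upfront_cost > local.upfront_cost:
        raise ValueError("overseas migration cost must exceed local cost")
    if not overseas.income_mean > local.income_mean:
        raise ValueError("overseas income mean must exceed local income mean")


@dataclass
class HouseholdState:
    """Mutable state of one household agent."""

    id: int
    wealth: float
    risk_aversion: float
    info_access: str  # "none" | "partial" | "full"
    neighbors: frozenset[int] = field(default_factory=frozenset)
    portfolio: frozenset[StrategyKind] = field(
        default_factory=lambda: frozenset({StrategyKind.SUBSISTENCE_CROP})
    )
    income_history: list[float] = field(default_factory=list)
    perceived: dict[StrategyKind, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wealth < 0:
            raise ValueError("wealth must be >= 0")
        if self.risk_aversion < 0:
            raise ValueError("risk_aversion must be >= 0")
        validate_portfolio(self.portfolio)


def validate_portfolio(portfolio: Iterable[StrategyKind]) -> frozenset[StrategyKind]:
    """A valid portfolio holds exactly one farming kind plus any migrations."""
    p = frozenset(portfolio)
    unknown = [k for k in p if not isinstance(k, StrategyKind)]
    if unknown:
        raise ValueError(f"unknown strategy kinds: {unknown}")
    n_farm = sum(1 for k in p if k.is_farming)
    if n_farm != 1:
        raise ValueError(f"portfolio must contain exactly one farming kind, got {n_farm}")
    return p


def canonical_portfolios() -> list[frozenset[StrategyKind]]:
    """The 8 valid portfolios in canonical tie-break order.

    Order: by farming kind (subsistence < cash), then migration subset
    ({}, {local}, {overseas}, {local, overseas}).
    """
    out = []
    mig_subsets = [
        frozenset(),
        frozenset({StrategyKind.LOCAL_MIGRATION}),
        frozenset({StrategyKind.OVERSEAS_MIGRATION}),
        frozenset(MIGRATION_KINDS),
    ]
    for farm in FARMING_KINDS:
        for mig in mig_subsets:
            out.append(frozenset({farm}) | mig)
    return out


@dataclass
class ModelParams:
    """Community-level parameters of the simulation.

    Defaults describe a 100-household community calibrated so that, in a
    stationary climate, local-migration uptake plateaus well before 2025
    while overseas uptake keeps growing through migrant-network cost
    feedback.
    """

    n_households: int = 100
    risk_aversion_distribution: tuple[str, dict] = ("gamma", {"shape": 2.0, "scale": 0.5})
    wealth_distribution: tuple[str, dict] = (
        "lognormal",
        {"mean": math.log(20.0), "sigma": 0.8},
    )
    government_signal_noise: float = 0.5
    #: cost-discount floor for local moves: a migrant contact can cover
    #: most of a local move (housing, job search)
    network_cost_floor: float = 0.2
    #: floor for overseas moves: visas, flights and recruitment fees are
    #: an irreducible cash cost no contact can waive
    overseas_cost_floor: float = 0.6
    aspiration_window: int = 4
    report_window: int = 8
    aspiration_ratio: float = 0.9
    neighbor_weight: float = 0.5
    gov_weight: float = 0.25
    subsistence_need: float = 10.0
    coping_buffer: float = 1.5  # wealth threshold, in multiples of subsistence_need
    #: migrant contacts at which the network cost discount saturates: the
    #: fraction fed to migration_cost is min(1, migrant_neighbors / this)
    cost_network_size: int = 10
    #: optional utility bonus for keeping the status quo portfolio
    #: (stickiness of established arrangements); disabled by default
    status_quo_premium: float = 0.0
    yield_sensitivity: float = 0.07  # crop-yield decline per degree C
    utility_form: str = "sd"  # "sd" -> mu - r*sigma; "variance" -> mu - r*sigma^2
    strategy_specs: dict[StrategyKind, StrategySpec] = field(
        default_factory=default_strategy_specs
    )

    def __post_init__(self) -> None:
        if self.n_households < 2:
            raise ValueError("n_households must be >= 2")
        if not 0 < self.network_cost_floor <= 1:
            raise ValueError("network_cost_floor must lie in (0, 1]")
        if self.utility_form not in ("sd", "variance"):
            raise ValueError("utility_form must be 'sd' or 'variance'")
        validate_strategy_specs(self.strategy_specs)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(n: int, topology: tuple[str, float], rng_seed: int) -> nx.Graph:
    """Build the community social network.

    Parameters
    ----------
    n
        Number of households (>= 2).
    topology
        ``("scale_free", avg_degree)`` for preferential attachment with a
        mixed attachment count targeting the given average degree, or
        ``("uniform", degree)`` for a random regular graph where every
        household has exactly ``degree`` neighbors (``degree = n - 1``
        yields the complete community graph).
    rng_seed
        Seed for the graph draw.

    Returns
    -------
    networkx.Graph
        Simple undirected graph on nodes ``0..n-1``.
    """
    if n < 2:
        raise ValueError("need at least 2 households")
    name, degree = topology
    if name == "uniform":
        d = int(degree)
        if d != degree or d < 0:
            raise ValueError("uniform degree must be a non-negative integer")
        if d > n - 1:
            raise ValueError(f"uniform degree {d} infeasible for n={n}")
        if (n * d) % 2 != 0:
            raise ValueError(f"degree sequence infeasible: n*degree={n * d} is odd")
        if d == n - 1:
            return nx.complete_graph(n)
        return nx.random_regular_graph(d, n, seed=int(rng_seed))
    if name == "scale_free":
        return _preferential_attachment(n, float(degree), rng_seed)
    raise ValueError(f"unknown topology {name!r}")


def _preferential_attachment(n: int, avg_degree: float, rng_seed: int) -> nx.Graph:
    """Preferential attachment with attachment count m drawn from {2, 3}.

    With P(m=2)=P(m=3)=1/2 the expected number of edges is ~2.5 per added
    node, so the mean degree lands near the scale-free target of 4.5.
    """
    rng = np.random.default_rng(int(rng_seed))
    g = nx.Graph()
    m0 = 3
    g.add_nodes_from(range(min(m0, n)))
    for i in range(1, min(m0, n)):
        g.add_edge(i - 1, i)
    # repeated-node list implements degree-proportional sampling
    targets: list[int] = []
    for u, v in g.edges():
        targets.extend((u, v))
    for new in range(m0, n):
        m = 2 if rng.random() < 0.5 else 3
        m = min(m, new)
        chosen: set[int] = set()
        while len(chosen) < m:
            pick = targets[rng.integers(len(targets))]
            chosen.add(pick)
        for c in chosen:
            g.add_edge(new, c)
            targets.extend((new, c))
    return g


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

def perceive(
    household: HouseholdState,
    neighbor_reports: Mapping[StrategyKind, Sequence[tuple[float, float]]],
    government_signal: Mapping[StrategyKind, tuple[float, float]],
    info_access: str | None = None,
    *,
    neighbor_weight: float = 0.5,
    gov_weight: float = 0.25,
) -> dict[StrategyKind, tuple[float, float]]:
    """Update a household's perceived income distributions.

    The new perception is a convex combination of the prior perception,
    the pooled neighbor reports (weight ``neighbor_weight`` when any
    report exists) and, under partial access, the government signal
    (weight ``gov_weight``).  Under full access the perception is replaced
    by the (government-known) true parameters; under no access the
    government term is omitted.  Kinds with no report and no government
    term keep their prior.
    """
    access = info_access if info_access is not None else household.info_access
    if access not in ("none", "partial", "full"):
        raise ValueError(f"unknown info_access {access!r}")
    if access == "full":
        return {k: tuple(government_signal[k]) for k in government_signal}

    out: dict[StrategyKind, tuple[float, float]] = dict(household.perceived)
    kinds = set(household.perceived) | set(neighbor_reports)
    if access == "partial":
        kinds |= set(government_signal)
    for k in kinds:
        prior = household.perceived.get(k)
        reports = list(neighbor_reports.get(k, ()))
        w_n = neighbor_weight if reports else 0.0
        w_g = gov_weight if (access == "partial" and k in government_signal) else 0.0
        if prior is None:
            # no prior: renormalise over the available sources
            total = w_n + w_g
            if total == 0:
                continue
            w_n, w_g, w_p = w_n / total, w_g / total, 0.0
            prior = (0.0, 0.0)
        else:
            w_p = 1.0 - w_n - w_g
        rep_mean = float(np.mean([m for m, _ in reports])) if reports else 0.0
        rep_sd = float(np.mean([s for _, s in reports])) if reports else 0.0
        gov = government_signal.get(k, (0.0, 0.0))
        mean = w_p * prior[0] + w_n * rep_mean + w_g * gov[0]
        sd = w_p * prior[1] + w_n * rep_sd + w_g * gov[1]
        out[k] = (mean, max(sd, 0.0))
    return out


# ---------------------------------------------------------------------------
# utility and feasibility
# ---------------------------------------------------------------------------

def portfolio_utility(
    portfolio: Iterable[StrategyKind],
    perceived: Mapping[StrategyKind, tuple[float, float]],
    risk_aversion: float,
    *,
    form: str = "sd",
) -> float:
    """Mean--variance utility of a portfolio under independent incomes.

    ``U = mu_p - r * sigma_p`` (default) where ``mu_p`` is the sum of the
    perceived means and ``sigma_p = sqrt(sum sd_k^2)``; with
    ``form="variance"`` the penalty is ``r * sigma_p^2``.
    """
    p = validate_portfolio(portfolio)
    missing = [k for k in p if k not in perceived]
    if missing:
        raise ValueError(f"no perceived distribution for {missing}")
    mu = sum(perceived[k][0] for k in p)
    var = sum(perceived[k][1] ** 2 for k in p)
    if form == "sd":
        return mu - risk_aversion * math.sqrt(var)
    if form == "variance":
        return mu - risk_aversion * var
    raise ValueError(f"unknown utility form {form!r}")


def portfolio_cost(
    portfolio: Iterable[StrategyKind],
    current: Iterable[StrategyKind],
    specs: Mapping[StrategyKind, StrategySpec],
    migration_costs: Mapping[StrategyKind, float],
) -> float:
    """Upfront cost of moving to ``portfolio`` from ``current``.

    Recurring (farming) costs are due every cycle; migration entry costs
    are due only for migration kinds newly added relative to ``current``.
    ``migration_costs`` holds the network-adjusted entry costs.
    """
    p = frozenset(portfolio)
    cur = frozenset(current)
    cost = 0.0
    for k in p:
        spec = specs[k]
        if spec.recurring:
            cost += spec.upfront_cost
        elif k not in cur:
            cost += float(migration_costs.get(k, spec.upfront_cost))
    return cost


def feasible_portfolios(
    household: HouseholdState,
    specs: Mapping[StrategyKind, StrategySpec],
    migration_costs: Mapping[StrategyKind, float],
) -> list[frozenset[StrategyKind]]:
    """All valid portfolios whose total upfront cost fits the budget.

    Returned in canonical order.  With a zero-cost subsistence strategy,
    ``{subsistence_crop}`` is always feasible.
    """
    out = []
    for p in canonical_portfolios():
        cost = portfolio_cost(p, household.portfolio, specs, migration_costs)
        if cost <= household.wealth + 1e-9:
            out.append(p)
    return out


def migration_cost(
    kind: StrategyKind,
    base_cost: float,
    network_migrant_fraction: float,
    floor: float,
) -> float:
    """Network-adjusted entry cost of a migration strategy.

    ``cost = base_cost * max(floor, 1 - network_migrant_fraction)``: a
    larger share of neighbors already engaged in the strategy lowers the
    entry cost, but never below ``floor * base_cost``.
    """
    if not kind.is_migration:
        raise ValueError(f"{kind} is not a migration strategy")
    if not 0 <= network_migrant_fraction <= 1:
        raise ValueError("network_migrant_fraction must lie in [0, 1]")
    if not 0 < floor <= 1:
        raise ValueError("floor must lie in (0, 1]")
    return base_cost * max(floor, 1.0 - network_migrant_fraction)


# ---------------------------------------------------------------------------
# satisficing and decision
# ---------------------------------------------------------------------------

def _trailing_mean(history: Sequence[float], window: int, end_offset: int = 0) -> float | None:
    """Mean of the last ``window`` entries ending ``end_offset`` from the end."""
    h = list(history)
    if end_offset:
        h = h[:-end_offset]
    if not h:
        return None
    return float(np.mean(h[-window:]))


def is_satisfied(
    household: HouseholdState,
    neighbor_trailing_means: Sequence[float],
    *,
    window: int = 4,
    aspiration_ratio: float = 0.9,
) -> bool:
    """Satisficing rule: keep the status quo unless income disappoints.

    A household is dissatisfied iff its trailing-``window`` mean income is
    below the median of its neighbors' trailing means, or below
    ``aspiration_ratio`` times its own previous trailing mean.  With no
    usable history the household is satisfied (nothing to compare).
    """
    own = _trailing_mean(household.income_history, window)
    if own is None:
        return True
    if neighbor_trailing_means:
        if own < float(np.median(neighbor_trailing_means)):
            return False
    prev = _trailing_mean(household.income_history, window, end_offset=1)
    if prev is not None and own < aspiration_ratio * prev:
        return False
    return True


def effective_perceived(
    perceived: Mapping[StrategyKind, tuple[float, float]],
    specs: Mapping[StrategyKind, StrategySpec],
) -> dict[StrategyKind, tuple[float, float]]:
    """Perceived distributions with recurring input costs netted from means."""
    out = {}
    for k, (m, s) in perceived.items():
        spec = specs.get(k)
        if spec is not None and spec.recurring:
            m = m - spec.upfront_cost
        out[k] = (m, s)
    return out


def decide(
    household: HouseholdState,
    neighbor_trailing_means: Sequence[float],
    specs: Mapping[StrategyKind, StrategySpec],
    migration_costs: Mapping[StrategyKind, float],
    *,
    window: int = 4,
    aspiration_ratio: float = 0.9,
    coping_wealth: float | None = None,
    utility_form: str = "sd",
    status_quo_premium: float = 0.0,
) -> frozenset[StrategyKind]:
    """Choose the next portfolio.

    Satisfied households keep the status quo.  Dissatisfied households
    (or households whose wealth has fallen below ``coping_wealth``)
    maximise :func:`portfolio_utility` -- evaluated on perceived means net
    of recurring costs -- over :func:`feasible_portfolios`.  The current
    portfolio enjoys ``status_quo_premium`` extra utility (an established
    arrangement is only abandoned for a clear improvement).  Ties are
    broken by lower upfront cost, then by canonical kind order.  A
    household in distress (wealth below ``coping_wealth``) restricts the
    choice to portfolios containing local migration whenever any such
    portfolio is feasible (ex-post coping migration).
    """
    distress = coping_wealth is not None and household.wealth < coping_wealth
    if not distress and is_satisfied(
        household,
        neighbor_trailing_means,
        window=window,
        aspiration_ratio=aspiration_ratio,
    ):
        return household.portfolio

    candidates = feasible_portfolios(household, specs, migration_costs)
    if distress:
        with_local = [p for p in candidates if StrategyKind.LOCAL_MIGRATION in p]
        if with_local:
            candidates = with_local
    eff = effective_perceived(household.perceived, specs)
    best = None
    best_u = -math.inf
    best_cost = math.inf
    tol = 1e-9
    for p in candidates:  # canonical order; first hit wins remaining ties
        u = portfolio_utility(p, eff, household.risk_aversion, form=utility_form)
        if p == household.portfolio:
            u += status_quo_premium
        cost = portfolio_cost(p, household.portfolio, specs, migration_costs)
        if u > best_u + tol or (abs(u - best_u) <= tol and cost < best_cost - tol):
            best, best_u, best_cost = p, u, cost
    assert best is not None  # {subsistence_crop} is always feasible
    return best
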