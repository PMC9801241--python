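"""Vectorised community simulation.

Runs the household ABM for one community over the full horizon with all
households advanced in lockstep numpy operations.  The per-household
semantics match the reference operations in :mod:`droughtmob.abm`
(perceive / satisficing / decide / migration_cost); the test suite checks
the engine's decisions against the per-household brute-force path.

Per-cycle order of events:

1. perception update from neighbor reports and the government signal;
2. satisficing check and (for dissatisfied or distressed households)
   portfolio re-optimisation, paying network-adjusted entry costs for
   newly adopted migration strategies;
3. income realisation under the cycle's climate (droughts zero farming
   incomes; warming scales mean yields), wealth update net of recurring
   input costs and subsistence consumption, truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from droughtmob.abm import (
    FARMING_KINDS,
    KIND_ORDER,
    MIGRATION_KINDS,
    ModelParams,
    StrategyKind,
    canonical_portfolios,
)
from droughtmob.climate import ClimatePath, yield_factor

__all__ = ["WorldState", "realize_cycle", "run_simulation", "SimulationResult"]

_K = len(KIND_ORDER)
_KIND_INDEX = {k: i for i, k in enumerate(KIND_ORDER)}
_FARM_IDX = np.array([_KIND_INDEX[k] for k in FARMING_KINDS])
_MIG_IDX = np.array([_KIND_INDEX[k] for k in MIGRATION_KINDS])
_LOCAL = _KIND_INDEX[StrategyKind.LOCAL_MIGRATION]

# (8, 4) boolean membership matrix of the canonical portfolios
_PORTFOLIOS = canonical_portfolios()
_P8 = np.zeros((len(_PORTFOLIOS), _K), dtype=bool)
for _p_i, _p in enumerate(_PORTFOLIOS):
    for _k in _p:
        _P8[_p_i, _KIND_INDEX[_k]] = True


@dataclass
class WorldState:
    """Array-backed state of the community at one cycle."""

    cycle_index: int
    wealth: np.ndarray  # (n,)
    risk_aversion: np.ndarray  # (n,)
    portfolio: np.ndarray  # (n, 4) bool
    perceived_mean: np.ndarray  # (n, 4)
    perceived_sd: np.ndarray  # (n, 4)
    adjacency: np.ndarray  # (n, n) bool, symmetric, hollow
    params: ModelParams

    @property
    def n(self) -> int:
        return len(self.wealth)

    def migrant_counts(self) -> dict[StrategyKind, int]:
        return {k: int(self.portfolio[:, _KIND_INDEX[k]].sum()) for k in MIGRATION_KINDS}


@dataclass
class SimulationResult:
    """Per-cycle outcomes of one run."""

    proportions: np.ndarray  # (n_cycles, 4) share of households holding each kind
    mean_wealth: np.ndarray  # (n_cycles,)
    seed: int

    def proportion(self, kind: StrategyKind) -> np.ndarray:
        return self.proportions[:, _KIND_INDEX[kind]]


def _realize_incomes(
    P: np.ndarray,
    true_mean: np.ndarray,
    true_sd: np.ndarray,
    yf: float,
    drought: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-household, per-strategy income components for one cycle.

    Gamma draws keep incomes non-negative with the specified mean/sd;
    warming scales mean farm yields by ``yf``; a drought zeroes farming
    components exactly.  Households draw only for strategies they hold.
    """
    n = P.shape[0]
    means = np.tile(true_mean, (n, 1))
    means[:, _FARM_IDX] *= yf
    sds = np.tile(true_sd, (n, 1))
    positive = (means > 0) & (sds > 0)
    shape = np.where(positive, (means / np.where(sds > 0, sds, 1.0)) ** 2, 1.0)
    scale = np.where(positive, sds**2 / np.where(means > 0, means, 1.0), 0.0)
    comp = np.where(positive, rng.gamma(shape) * scale, means)
    if drought:
        comp[:, _FARM_IDX] = 0.0
    return np.where(P, comp, 0.0)


def realize_cycle(
    world: WorldState,
    climate_cycle: tuple[float, bool],
    rng: np.random.Generator,
) -> tuple[WorldState, np.ndarray]:
    """Realise one cycle's incomes and update wealth on a world state.

    Returns the advanced world state and the per-household, per-strategy
    income components.  Wealth update: income minus recurring input
    costs minus subsistence consumption, truncated at zero.
    """
    params = world.params
    specs = params.strategy_specs
    true_mean = np.array([specs[k].income_mean for k in KIND_ORDER])
    true_sd = np.array([specs[k].income_sd for k in KIND_ORDER])
    recurring = np.array(
        [specs[k].upfront_cost if specs[k].recurring else 0.0 for k in KIND_ORDER]
    )
    anomaly, drought = climate_cycle
    yf_warm = yield_factor(float(anomaly), False, params.yield_sensitivity)
    comp = _realize_incomes(world.portfolio, true_mean, true_sd, yf_warm, bool(drought), rng)
    income = comp.sum(axis=1)
    rec_due = (recurring[None, :] * world.portfolio).sum(axis=1)
    wealth = np.maximum(world.wealth + income - rec_due - params.subsistence_need, 0.0)
    new = WorldState(
        cycle_index=world.cycle_index + 1,
        wealth=wealth,
        risk_aversion=world.risk_aversion,
        portfolio=world.portfolio,
        perceived_mean=world.perceived_mean,
        perceived_sd=world.perceived_sd,
        adjacency=world.adjacency,
        params=params,
    )
    return new, comp


def _draw(dist: tuple[str, dict], size: int, rng: np.random.Generator) -> np.ndarray:
    name, kw = dist
    if name == "gamma":
        return rng.gamma(kw["shape"], kw["scale"], size)
    if name == "lognormal":
        return rng.lognormal(kw["mean"], kw["sigma"], size)
    if name == "constant":
        return np.full(size, float(kw["value"]))
    raise ValueError(f"unknown distribution {name!r}")


def run_simulation(
    params: ModelParams,
    graph: nx.Graph,
    info_access: str,
    climate: ClimatePath,
    seed: int,
) -> SimulationResult:
    """Run one community for the full climate path.

    Deterministic given ``(params, graph, info_access, climate, seed)``.
    """
    if info_access not in ("none", "partial", "full"):
        raise ValueError(f"unknown info_access {info_access!r}")
    rng = np.random.default_rng(int(seed))
    n = params.n_households
    if graph.number_of_nodes() != n:
        raise ValueError("graph size does not match n_households")
    T = len(climate)

    specs = params.strategy_specs
    true_mean = np.array([specs[k].income_mean for k in KIND_ORDER])
    true_sd = np.array([specs[k].income_sd for k in KIND_ORDER])
    recurring = np.array(
        [specs[k].upfront_cost if specs[k].recurring else 0.0 for k in KIND_ORDER]
    )
    entry_base = np.array(
        [0.0 if specs[k].recurring else specs[k].upfront_cost for k in KIND_ORDER]
    )
    is_farm = np.zeros(_K, dtype=bool)
    is_farm[_FARM_IDX] = True

    A = nx.to_numpy_array(graph, nodelist=range(n), dtype=bool)
    np.fill_diagonal(A, False)
    deg = A.sum(axis=1)
    Aself = A.copy()
    np.fill_diagonal(Aself, True)  # households pool their own experience too
    A_nan = np.where(A, 1.0, np.nan)  # for vectorised neighbor medians

    # draws fixed at t0 (order matters for cross-scenario seed pairing)
    wealth = _draw(params.wealth_distribution, n, rng)
    r = _draw(params.risk_aversion_distribution, n, rng)

    # perceptions start at the climatological truth
    perc_mean = np.tile(true_mean, (n, 1)).astype(float)
    perc_sd = np.tile(true_sd, (n, 1)).astype(float)

    # initial portfolios: best farming kind alone (no migrants yet)
    eff0 = true_mean - recurring
    u_sub = eff0[0] - r * true_sd[0]
    u_cash = eff0[1] - r * true_sd[1]
    cash_ok = (u_cash > u_sub) & (wealth >= recurring[1])
    P = np.zeros((n, _K), dtype=bool)
    P[:, 0] = ~cash_ok
    P[:, 1] = cash_ok

    RW = params.report_window
    AW = params.aspiration_window
    comp_hist = np.zeros((RW, n, _K))
    engaged_hist = np.zeros((RW, n, _K), dtype=bool)
    total_hist = np.zeros((RW, n))
    filled = 0

    need = params.subsistence_need
    coping_wealth = params.coping_buffer * need
    k_yield = params.yield_sensitivity
    var_form = params.utility_form == "variance"

    proportions = np.zeros((T, _K))
    mean_wealth = np.zeros(T)

    for t in range(T):
        anomaly = float(climate.temp_anomaly[t])
        drought = bool(climate.drought_flag[t])
        yf = yield_factor(anomaly, False, k_yield)  # climatological expectation

        # current true parameters as known to an accurate source: warming
        # scales farming means, droughts are not anticipated
        gov_true_mean = true_mean.copy()
        gov_true_mean[_FARM_IDX] *= yf

        if t >= 1:
            # ---- perception update -------------------------------------
            if info_access == "full":
                perc_mean = np.tile(gov_true_mean, (n, 1))
                perc_sd = np.tile(true_sd, (n, 1))
            else:
                h = min(filled, RW)
                eng = engaged_hist[:h]  # (h, n, K)
                cnt_cycles = eng.sum(axis=0)  # (n, K)
                has_rep = cnt_cycles > 0
                comp = comp_hist[:h]
                s1 = np.where(eng, comp, 0.0).sum(axis=0)
                s2 = np.where(eng, comp**2, 0.0).sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    rep_mean = np.where(has_rep, s1 / np.maximum(cnt_cycles, 1), 0.0)
                    rep_var = np.maximum(
                        s2 / np.maximum(cnt_cycles, 1) - rep_mean**2, 0.0
                    )
                rep_sd = np.sqrt(rep_var)
                # pool over self + neighbors
                pooled_n = Aself @ has_rep.astype(float)
                pooled_mean = np.where(
                    pooled_n > 0, (Aself @ np.where(has_rep, rep_mean, 0.0)) / np.maximum(pooled_n, 1), 0.0
                )
                pooled_sd = np.where(
                    pooled_n > 0, (Aself @ np.where(has_rep, rep_sd, 0.0)) / np.maximum(pooled_n, 1), 0.0
                )
                w_n = np.where(pooled_n > 0, params.neighbor_weight, 0.0)
                if info_access == "partial":
                    gov_mean = gov_true_mean + rng.normal(
                        0.0, params.government_signal_noise, _K
                    )
                    gov_sd = true_sd
                    w_g = np.full((n, _K), params.gov_weight)
                else:
                    gov_mean = np.zeros(_K)
                    gov_sd = np.zeros(_K)
                    w_g = np.zeros((n, _K))
                w_p = 1.0 - w_n - w_g
                perc_mean = w_p * perc_mean + w_n * pooled_mean + w_g * gov_mean
                perc_sd = np.maximum(
                    w_p * perc_sd + w_n * pooled_sd + w_g * gov_sd, 0.0
                )

            # ---- satisficing -------------------------------------------
            h4 = min(filled, AW)
            own = total_hist[:h4].mean(axis=0)
            dissatisfied = np.zeros(n, dtype=bool)
            trail = own  # trailing mean ending at t-1
            with np.errstate(invalid="ignore"):
                med = np.nanmedian(A_nan * trail[None, :], axis=1)
            med = np.where(np.isnan(med), -np.inf, med)
            dissatisfied |= trail < med
            if filled >= 2:
                hprev = min(filled - 1, AW)
                prev = total_hist[1 : 1 + hprev].mean(axis=0)
                dissatisfied |= trail < params.aspiration_ratio * prev
            distress = wealth < coping_wealth
            deciders = dissatisfied | distress

            if deciders.any():
                # ---- network-adjusted entry costs ----------------------
                # migrant-contact help saturates at cost_network_size ties
                nbr_frac = np.zeros((n, _K))
                for k in _MIG_IDX:
                    cnt = A @ P[:, k].astype(float)
                    nbr_frac[:, k] = np.minimum(cnt / params.cost_network_size, 1.0)
                floors = np.zeros(_K)
                floors[_KIND_INDEX[StrategyKind.LOCAL_MIGRATION]] = params.network_cost_floor
                floors[_KIND_INDEX[StrategyKind.OVERSEAS_MIGRATION]] = params.overseas_cost_floor
                entry = entry_base * np.maximum(floors[None, :], 1.0 - nbr_frac)
                entry = np.where(P, 0.0, entry)  # already-held kinds cost nothing
                entry[:, _FARM_IDX] = 0.0

                # ---- vectorised argmax over the 8 portfolios -----------
                eff_mean = perc_mean - recurring[None, :]
                mu = eff_mean @ _P8.T  # (n, 8)
                var = (perc_sd**2) @ _P8.T
                risk = var if var_form else np.sqrt(var)
                U = mu - r[:, None] * risk
                # status-quo premium on each household's current portfolio
                cur_idx = (P[:, None, :] == _P8[None, :, :]).all(axis=2).argmax(axis=1)
                U[np.arange(n), cur_idx] += params.status_quo_premium
                rec_cost = (recurring[None, :] * _P8).sum(axis=1)  # (8,)
                cost = entry @ _P8.T + rec_cost[None, :]
                feas = cost <= wealth[:, None] + 1e-9
                has_local = _P8[:, _LOCAL]
                coping_rows = distress & (feas & has_local[None, :]).any(axis=1)
                use = np.where(
                    coping_rows[:, None], feas & has_local[None, :], feas
                )
                tol = 1e-9
                best_idx = np.zeros(n, dtype=int)
                best_u = np.full(n, -np.inf)
                best_c = np.full(n, np.inf)
                for p_i in range(_P8.shape[0]):
                    ok = use[:, p_i]
                    up = np.where(ok, U[:, p_i], -np.inf)
                    cp = cost[:, p_i]
                    tied = ok & np.isfinite(best_u) & (np.abs(U[:, p_i] - best_u) <= tol)
                    better = (up > best_u + tol) | (tied & (cp < best_c - tol))
                    best_idx = np.where(better, p_i, best_idx)
                    best_c = np.where(better, cp, best_c)
                    best_u = np.where(better, up, best_u)
                new_P = _P8[best_idx]
                changed = deciders
                # pay entry costs of newly adopted migration strategies
                newly = new_P & ~P & ~is_farm[None, :]
                pay = (entry * newly).sum(axis=1)
                wealth = np.where(changed, np.maximum(wealth - pay, 0.0), wealth)
                P = np.where(changed[:, None], new_P, P)

        # ---- realise incomes -------------------------------------------
        comp = _realize_incomes(P, true_mean, true_sd, yf, drought, rng)
        income = comp.sum(axis=1)
        rec_due = (recurring[None, :] * P).sum(axis=1)
        wealth = np.maximum(wealth + income - rec_due - need, 0.0)

        # roll history buffers (index 0 = most recent)
        comp_hist = np.roll(comp_hist, 1, axis=0)
        engaged_hist = np.roll(engaged_hist, 1, axis=0)
        total_hist = np.roll(total_hist, 1, axis=0)
        comp_hist[0] = comp
        engaged_hist[0] = P
        total_hist[0] = income
        filled = min(filled + 1, RW)

        proportions[t] = P.mean(axis=0)
        mean_wealth[t] = wealth.mean()

    return SimulationResult(proportions=proportions, mean_wealth=mean_wealth, seed=int(seed))
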