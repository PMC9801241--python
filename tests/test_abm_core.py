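"""Household-level ABM operations: networks, perception, utility, choice."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from droughtmob.abm import (
    FARMING_KINDS,
    KIND_ORDER,
    MIGRATION_KINDS,
    HouseholdState,
    ModelParams,
    StrategyKind,
    StrategySpec,
    build_network,
    canonical_portfolios,
    decide,
    default_strategy_specs,
    feasible_portfolios,
    is_satisfied,
    migration_cost,
    perceive,
    portfolio_cost,
    portfolio_utility,
)

SUB = StrategyKind.SUBSISTENCE_CROP
CASH = StrategyKind.CASH_CROP
LOCAL = StrategyKind.LOCAL_MIGRATION
OVERSEAS = StrategyKind.OVERSEAS_MIGRATION


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_uniform_99_is_complete_graph(self):
        g = build_network(100, ("uniform", 99), rng_seed=0)
        degrees = [d for _, d in g.degree()]
        assert degrees == [99] * 100

    def test_uniform_1_is_perfect_matching(self):
        g = build_network(100, ("uniform", 1), rng_seed=0)
        degrees = sorted(d for _, d in g.degree())
        assert degrees == [1] * 100
        assert g.number_of_edges() == 50

    def test_scale_free_grand_mean_degree(self):
        # grand mean over 200 seeds within +/-10% of the 4.5 target
        means = []
        for seed in range(200):
            g = build_network(100, ("scale_free", 4.5), rng_seed=seed)
            means.append(2 * g.number_of_edges() / 100)
        grand = float(np.mean(means))
        assert 4.05 <= grand <= 4.95

    def test_no_self_loops_and_symmetric(self):
        g = build_network(50, ("scale_free", 4.5), rng_seed=3)
        assert all(u != v for u, v in g.edges())

    @pytest.mark.parametrize(
        "n,topology",
        [(100, ("uniform", 100)), (5, ("uniform", 3)), (1, ("uniform", 0))],
    )
    def test_infeasible_degree_sequences_raise(self, n, topology):
        with pytest.raises(ValueError):
            build_network(n, topology, rng_seed=0)


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

def _household(**kw):
    defaults = dict(
        id=0,
        wealth=50.0,
        risk_aversion=1.0,
        info_access="partial",
        portfolio=frozenset({SUB}),
        perceived={k: (s.income_mean, s.income_sd) for k, s in default_strategy_specs().items()},
    )
    defaults.update(kw)
    return HouseholdState(**defaults)


class TestPerceive:
    def test_full_access_equals_truth(self):
        hh = _household(perceived={SUB: (3.0, 1.0)})
        truth = {k: (default_strategy_specs()[k].income_mean,
                     default_strategy_specs()[k].income_sd) for k in KIND_ORDER}
        got = perceive(hh, {SUB: [(99.0, 99.0)]}, truth, "full")
        assert got == truth

    def test_no_access_no_reports_is_identity(self):
        prior = {SUB: (7.0, 2.0), LOCAL: (1.0, 1.0)}
        hh = _household(perceived=dict(prior), info_access="none")
        got = perceive(hh, {}, {SUB: (10.0, 3.0)}, "none")
        assert got == prior

    def test_single_report_half_weight(self):
        # prior mean 10, one neighbor reports 20, no gov term -> 15
        hh = _household(perceived={SUB: (10.0, 3.0)}, info_access="none")
        got = perceive(hh, {SUB: [(20.0, 3.0)]}, {}, "none", neighbor_weight=0.5)
        assert got[SUB][0] == pytest.approx(15.0)

    def test_partial_blend_is_convex_combination(self):
        hh = _household(perceived={SUB: (10.0, 2.0)})
        got = perceive(
            hh, {SUB: [(20.0, 4.0)]}, {SUB: (12.0, 3.0)}, "partial",
            neighbor_weight=0.5, gov_weight=0.25,
        )
        assert got[SUB][0] == pytest.approx(0.25 * 10 + 0.5 * 20 + 0.25 * 12)
        assert got[SUB][1] == pytest.approx(0.25 * 2 + 0.5 * 4 + 0.25 * 3)


# ---------------------------------------------------------------------------
# utility
# ---------------------------------------------------------------------------

class TestPortfolioUtility:
    def test_risk_neutral_is_total_mean(self):
        perceived = {SUB: (8.0, 3.0), LOCAL: (6.0, 4.0)}
        assert portfolio_utility({SUB, LOCAL}, perceived, 0.0) == pytest.approx(14.0)

    def test_zero_sd_removes_risk_penalty(self):
        perceived = {SUB: (8.0, 0.0), LOCAL: (6.0, 0.0)}
        for r in (0.0, 1.0, 10.0):
            assert portfolio_utility({SUB, LOCAL}, perceived, r) == pytest.approx(14.0)

    def test_quadrature_example(self):
        # means (8, 6), sds (3, 4), r = 1: 14 - sqrt(9 + 16) = 9
        perceived = {SUB: (8.0, 3.0), LOCAL: (6.0, 4.0)}
        assert portfolio_utility({SUB, LOCAL}, perceived, 1.0) == pytest.approx(9.0)

    def test_invalid_portfolios_raise(self):
        perceived = {k: (1.0, 1.0) for k in KIND_ORDER}
        with pytest.raises(ValueError):
            portfolio_utility({LOCAL}, perceived, 1.0)  # no farming kind
        with pytest.raises(ValueError):
            portfolio_utility({SUB, CASH}, perceived, 1.0)  # two farming kinds

    @given(st.floats(0, 10), st.floats(0.1, 10))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_decreasing_in_risk_aversion(self, r, dr):
        perceived = {SUB: (8.0, 3.0), LOCAL: (6.0, 4.0)}
        u1 = portfolio_utility({SUB, LOCAL}, perceived, r)
        u2 = portfolio_utility({SUB, LOCAL}, perceived, r + dr)
        assert u2 < u1

    def test_variance_penalty_form(self):
        perceived = {SUB: (8.0, 3.0)}
        assert portfolio_utility({SUB}, perceived, 0.5, form="variance") == pytest.approx(
            8.0 - 0.5 * 9.0
        )


# ---------------------------------------------------------------------------
# feasibility and migration cost
# ---------------------------------------------------------------------------

class TestFeasiblePortfolios:
    specs = default_strategy_specs()

    def mig_costs(self):
        return {k: self.specs[k].upfront_cost for k in MIGRATION_KINDS}

    def test_zero_wealth_leaves_only_subsistence(self):
        hh = _household(wealth=0.0)
        assert feasible_portfolios(hh, self.specs, self.mig_costs()) == [frozenset({SUB})]

    def test_ample_wealth_gives_all_eight(self):
        hh = _household(wealth=1e6)
        got = feasible_portfolios(hh, self.specs, self.mig_costs())
        assert len(got) == 8
        assert set(got) == set(canonical_portfolios())

    def test_mid_wealth_excludes_overseas(self):
        # wealth covers local entry but not overseas entry
        hh = _household(wealth=30.0)
        got = feasible_portfolios(hh, self.specs, self.mig_costs())
        assert all(OVERSEAS not in p for p in got)
        assert any(LOCAL in p for p in got)

    def test_already_held_migration_is_free(self):
        hh = _household(wealth=0.0, portfolio=frozenset({SUB, LOCAL}))
        got = feasible_portfolios(hh, self.specs, self.mig_costs())
        assert frozenset({SUB, LOCAL}) in got


class TestMigrationCost:
    def test_no_network_effect(self):
        assert migration_cost(LOCAL, 12.0, 0.0, 0.5) == pytest.approx(12.0)

    def test_floor_binds_at_full_prevalence(self):
        assert migration_cost(OVERSEAS, 100.0, 1.0, 0.5) == pytest.approx(50.0)

    def test_farming_kind_raises(self):
        with pytest.raises(ValueError):
            migration_cost(SUB, 10.0, 0.0, 0.5)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0.01, 1), st.floats(0, 1000)
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_nonincreasing_and_floored(self, f1, f2, floor, base):
        lo, hi = sorted((f1, f2))
        c_lo = migration_cost(LOCAL, base, lo, floor)
        c_hi = migration_cost(LOCAL, base, hi, floor)
        assert c_hi <= c_lo + 1e-12
        assert c_hi >= floor * base - 1e-12


# ---------------------------------------------------------------------------
# satisficing and decision vs brute-force oracle
# ---------------------------------------------------------------------------

def oracle_decide(household, specs, migration_costs):
    """Independent exhaustive argmax over all valid feasible portfolios."""
    best, best_key = None, None
    for p in canonical_portfolios():
        cost = 0.0
        for k in p:
            if specs[k].recurring:
                cost += specs[k].upfront_cost
            elif k not in household.portfolio:
                cost += migration_costs[k]
        if cost > household.wealth + 1e-9:
            continue
        mu = sum(
            household.perceived[k][0] - (specs[k].upfront_cost if specs[k].recurring else 0.0)
            for k in p
        )
        sigma = math.sqrt(sum(household.perceived[k][1] ** 2 for k in p))
        u = mu - household.risk_aversion * sigma
        key = (-round(u, 9), round(cost, 9))
        if best_key is None or key < best_key:
            best, best_key = p, key
    return best


def _dissatisfied_household(**kw):
    kw.setdefault("income_history", [10.0, 10.0, 0.0, 0.0])
    return _household(**kw)


class TestDecide:
    specs = default_strategy_specs()

    def mig_costs(self):
        return {k: self.specs[k].upfront_cost for k in MIGRATION_KINDS}

    def test_satisfied_household_keeps_status_quo(self):
        hh = _household(income_history=[10.0] * 8, portfolio=frozenset({SUB}))
        got = decide(hh, [5.0, 5.0, 5.0], self.specs, self.mig_costs())
        assert got == frozenset({SUB})

    def test_risk_neutral_takes_maximal_net_mean(self):
        hh = _dissatisfied_household(risk_aversion=0.0, wealth=1e6)
        got = decide(hh, [20.0] * 3, self.specs, self.mig_costs())
        assert got == oracle_decide(hh, self.specs, self.mig_costs())
        # all four strategies pay a positive net mean at this calibration
        assert got == frozenset({CASH, LOCAL, OVERSEAS})

    def test_budget_excludes_overseas(self):
        hh = _dissatisfied_household(risk_aversion=0.0, wealth=30.0)
        got = decide(hh, [20.0] * 3, self.specs, self.mig_costs())
        assert OVERSEAS not in got
        assert got == oracle_decide(hh, self.specs, self.mig_costs())

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            perceived = {
                k: (float(rng.uniform(-5, 15)), float(rng.uniform(0, 8)))
                for k in KIND_ORDER
            }
            hh = _dissatisfied_household(
                wealth=float(rng.uniform(0, 200)),
                risk_aversion=float(rng.gamma(2.0, 0.5)),
                perceived=perceived,
                portfolio=frozenset({SUB}),
            )
            got = decide(hh, [20.0] * 3, self.specs, self.mig_costs())
            assert got == oracle_decide(hh, self.specs, self.mig_costs())

    def test_distress_forces_local_when_affordable(self):
        hh = _dissatisfied_household(wealth=15.0, risk_aversion=5.0)
        got = decide(
            hh, [20.0] * 3, self.specs, self.mig_costs(), coping_wealth=20.0
        )
        assert LOCAL in got

    def test_satisficing_rule_comparators(self):
        hh = _household(income_history=[10.0, 10.0, 10.0, 10.0, 10.0])
        # above neighbors' median and own aspiration -> satisfied
        assert is_satisfied(hh, [8.0, 9.0, 7.0])
        # below neighbors' median -> dissatisfied
        assert not is_satisfied(hh, [12.0, 13.0, 14.0])
        # income collapse below 0.9 * previous trailing mean -> dissatisfied
        hh2 = _household(income_history=[10.0] * 4 + [0.0] * 4)
        assert not is_satisfied(hh2, [])


class TestSpecsAndParams:
    def test_default_specs_orderings(self):
        specs = default_strategy_specs()
        assert specs[OVERSEAS].upfront_cost > specs[LOCAL].upfront_cost
        assert specs[OVERSEAS].income_mean > specs[LOCAL].income_mean
        assert all(specs[k].income_sd >= 0 for k in KIND_ORDER)
        assert all(specs[k].recurring == k.is_farming for k in KIND_ORDER)

    def test_model_params_validation(self):
        with pytest.raises(ValueError):
            ModelParams(n_households=1)
        with pytest.raises(ValueError):
            ModelParams(network_cost_floor=0.0)
        with pytest.raises(ValueError):
            StrategySpec(SUB, -1.0, 10.0, 3.0, recurring=True)

    def test_portfolio_cost_counts_new_migrations_only(self):
        specs = default_strategy_specs()
        costs = {LOCAL: 8.0, OVERSEAS: 90.0}
        c = portfolio_cost({CASH, LOCAL, OVERSEAS}, {SUB, LOCAL}, specs, costs)
        assert c == pytest.approx(specs[CASH].upfront_cost + 90.0)
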