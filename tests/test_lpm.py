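"""Panel construction and linear-probability estimation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from droughtmob.lpm import (
    LPMEstimate,
    build_design,
    build_panel,
    fit_compounding,
    fit_heterogeneity,
    fit_lpm,
    fit_spillover,
)
from droughtmob.synth import PanelGenSpec, gen_adjacency, gen_panel


@pytest.fixture(scope="module")
def synthetic_panel():
    # community covariates need a non-trivial cross-section to stay
    # identified after state-year demeaning
    from droughtmob.synth import WeatherGenSpec, gen_daily_weather
    from droughtmob.weather import add_neighbor_dry, aggregate_all_seasons, classify_panel

    daily, communities = gen_daily_weather(
        WeatherGenSpec(n_communities=20, n_states=6, years=(1980, 2000), seed=5)
    )
    seasons = aggregate_all_seasons(
        daily, dict(zip(communities["community_id"], communities["state"]))
    )
    cats = add_neighbor_dry(classify_panel(seasons), gen_adjacency(20, seed=5))
    spec = PanelGenSpec(
        n_persons=1500,
        years=(1991, 2000),
        beta_dry_t1=0.01,
        beta_dry_x_no_irrigation=0.01,
        seed=5,
    )
    return gen_panel(spec, cats, communities)


def _person_histories():
    """Three hand-enumerable person histories.

    A migrates in the first observed year (1 row); B never migrates over
    10 years (10 rows); C migrates in year 3 of 5 (3 rows).
    """
    rows = []
    rows.append(dict(person_id="A", year=1995, migrated=1))
    for y in range(1991, 2001):
        rows.append(dict(person_id="B", year=y, migrated=0))
    for i, y in enumerate(range(1993, 1998)):
        rows.append(dict(person_id="C", year=y, migrated=int(i == 2)))
    df = pd.DataFrame(rows)
    df["household_id"] = df["person_id"]
    df["community_id"] = 0
    df["state_id"] = 0
    return df


def _categories(years):
    return pd.DataFrame(
        {
            "community_id": 0,
            "year": list(years),
            "precip_category": "normal",
            "temp_category": "normal",
        }
    )


class TestBuildPanel:
    def test_risk_set_row_counts_match_hand_enumeration(self):
        panel = build_panel(_person_histories(), _categories(range(1988, 2001)))
        counts = panel.groupby("person_id").size()
        assert counts["A"] == 1
        assert counts["B"] == 10
        assert counts["C"] == 3
        assert panel.groupby("person_id")["migrated"].sum().tolist() == [1, 0, 1]

    def test_lag_two_requires_coverage(self):
        panel = build_panel(
            _person_histories(), _categories(range(1988, 2001)), lags={1, 2}
        )
        assert {"dry_t1", "dry_t2"} <= set(panel.columns)

    def test_missing_lagged_weather_lists_offenders(self):
        with pytest.raises(ValueError, match="missing lag-1"):
            build_panel(_person_histories(), _categories(range(1995, 2001)))

    def test_unsupported_lags_raise(self):
        with pytest.raises(ValueError):
            build_panel(_person_histories(), _categories(range(1988, 2001)), lags={3})


class TestFitLPM:
    def test_tiny_regression_matches_closed_form(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        panel = pd.DataFrame(
            {"x": x, "migrated": y, "community_id": [0, 0, 1, 1, 2, 2]}
        )
        est = fit_lpm(panel, ["x"], fe=None)
        beta_hand = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert est.params["x"] == pytest.approx(beta_hand, abs=1e-12)

    def test_constant_outcome_gives_zero_slopes(self):
        rng = np.random.default_rng(0)
        panel = pd.DataFrame(
            {
                "x": rng.normal(size=40),
                "migrated": 0.0,
                "community_id": np.repeat(np.arange(8), 5),
                "state_id": 0,
                "year": np.tile(np.arange(5), 8),
            }
        )
        est = fit_lpm(panel, ["x"])
        assert est.params["x"] == pytest.approx(0.0, abs=1e-12)
        assert est.r2 == 0.0
        assert est.outcome_degenerate

    def test_absorbed_fe_matches_dummy_fit(self, synthetic_panel):
        """Demeaned and dummy-variable fits agree to 1e-8 (criterion oracle)."""
        panel = synthetic_panel
        X = build_design(panel, include_controls=False)
        est = fit_lpm(panel, X, cr2=False)

        cells = pd.get_dummies(
            panel["state_id"].astype(str) + "_" + panel["year"].astype(str),
            dtype=float,
        )
        bigX = pd.concat([X.reset_index(drop=True), cells.reset_index(drop=True)], axis=1)
        sm_fit = sm.OLS(panel["migrated"].to_numpy(), bigX.to_numpy()).fit(
            cov_type="cluster",
            cov_kwds={"groups": panel["community_id"].to_numpy()},
        )
        k = X.shape[1]
        assert np.allclose(est.params.to_numpy(), sm_fit.params[:k], atol=1e-8)
        assert np.allclose(est.se.to_numpy(), sm_fit.bse[:k], rtol=1e-6)
        assert est.r2 == pytest.approx(sm_fit.rsquared, abs=1e-8)

    def test_singleton_clusters_equal_hc1(self):
        rng = np.random.default_rng(1)
        n = 60
        panel = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "z": rng.normal(size=n),
                "migrated": rng.integers(0, 2, n).astype(float),
                "community_id": np.arange(n),  # one observation per cluster
            }
        )
        est = fit_lpm(panel, ["x", "z"], fe=None, cr2=False)
        hc1 = sm.OLS(
            panel["migrated"].to_numpy(),
            sm.add_constant(panel[["x", "z"]].to_numpy()),
        ).fit(cov_type="HC1")
        # with singleton clusters the CR1 factor G/(G-1)*(N-1)/(N-K)
        # collapses to the HC1 factor N/(N-K)
        assert np.allclose(est.se.to_numpy(), hc1.bse[1:], rtol=1e-8)

    def test_singular_design_names_collinear_columns(self, synthetic_panel):
        panel = synthetic_panel.copy()
        panel["dry_copy"] = panel["dry_t1"]
        with pytest.raises(np.linalg.LinAlgError, match="dry"):
            fit_lpm(panel, ["dry_t1", "dry_copy"])

    def test_single_cluster_raises(self):
        panel = pd.DataFrame(
            {"x": [0.0, 1.0], "migrated": [0, 1], "community_id": [0, 0]}
        )
        with pytest.raises(ValueError, match="clusters"):
            fit_lpm(panel, ["x"], fe=None)

    def test_cr2_matches_dense_reference(self):
        # subspace CR2 equals the direct (I - H_g)^{-1/2} computation
        rng = np.random.default_rng(4)
        n, k, G = 120, 3, 12
        panel = pd.DataFrame(
            rng.normal(size=(n, k)), columns=["x1", "x2", "x3"]
        )
        panel["migrated"] = (rng.random(n) < 0.3).astype(float)
        panel["community_id"] = rng.integers(0, G, n)
        est = fit_lpm(panel, ["x1", "x2", "x3"], fe=None, cr2=True)

        X = panel[["x1", "x2", "x3"]].to_numpy()
        Xd = X - X.mean(axis=0)
        y = panel["migrated"].to_numpy()
        yd = y - y.mean()
        XtX_inv = np.linalg.inv(Xd.T @ Xd)
        beta = XtX_inv @ Xd.T @ yd
        e = yd - Xd @ beta
        meat = np.zeros((k, k))
        for g in range(G):
            idx = panel.index[panel["community_id"] == g].to_numpy()
            Xg, eg = Xd[idx], e[idx]
            Hg = Xg @ XtX_inv @ Xg.T
            w, V = np.linalg.eigh(np.eye(len(idx)) - Hg)
            Ag = (V * (1.0 / np.sqrt(np.maximum(w, 1e-10)))) @ V.T
            s = Xg.T @ (Ag @ eg)
            meat += np.outer(s, s)
        se_ref = np.sqrt(np.diag(XtX_inv @ meat @ XtX_inv))
        assert np.allclose(est.se.to_numpy(), se_ref, rtol=1e-8)

    def test_cluster_robust_coverage_on_clustered_errors(self):
        """95% CIs on a pure intra-cluster-correlated design cover at
        their nominal rate (93 clusters, 200 replicates)."""
        rng = np.random.default_rng(12)
        G, m, beta = 93, 50, 0.5
        cover = 0
        reps = 200
        for _ in range(reps):
            cluster_id = np.repeat(np.arange(G), m)
            x = rng.normal(size=G * m) + np.repeat(rng.normal(0, 0.5, G), m)
            eps = rng.normal(0, 1, G * m) + np.repeat(rng.normal(0, 0.7, G), m)
            y = beta * x + eps
            panel = pd.DataFrame(
                {"x": x, "migrated": y, "community_id": cluster_id}
            )
            est = fit_lpm(panel, ["x"], fe=None)
            ci = est.conf_int().loc["x"]
            cover += ci["low"] <= beta <= ci["high"]
        assert 0.92 <= cover / reps <= 0.98

    def test_conf_int_brackets_estimate(self, synthetic_panel):
        est = fit_lpm(synthetic_panel, build_design(synthetic_panel))
        ci = est.conf_int()
        assert (ci["low"] <= est.params).all()
        assert (est.params <= ci["high"]).all()


class TestHeterogeneity:
    def test_interaction_terms_present(self, synthetic_panel):
        est = fit_heterogeneity(synthetic_panel, "no_irrigation")
        assert "dry_x_no_irrigation" in est.params.index
        est_p = fit_heterogeneity(synthetic_panel, "properties")
        assert {"dry_x_properties_medium", "dry_x_properties_high"} <= set(
            est_p.params.index
        )

    def test_constant_moderator_raises(self, synthetic_panel):
        panel = synthetic_panel.copy()
        panel["no_irrigation"] = 0
        with pytest.raises(ValueError, match="constant"):
            fit_heterogeneity(panel, "no_irrigation")

    def test_unknown_moderator_raises(self, synthetic_panel):
        with pytest.raises(ValueError):
            fit_heterogeneity(synthetic_panel, "altitude")


class TestCompoundingAndSpillover:
    def test_compounding_fits_both_strata(self, synthetic_panel):
        out = fit_compounding(synthetic_panel)
        assert set(out) == {"low", "high"}
        for est in out.values():
            assert {"dry_t1", "dry_t2"} <= set(est.params.index)

    def test_compounding_requires_lag_two(self, synthetic_panel):
        panel = synthetic_panel.drop(columns=["dry_t2"])
        with pytest.raises(ValueError, match="lag-2"):
            fit_compounding(panel)

    def test_spillover_fits_with_neighbor_term(self, synthetic_panel):
        out = fit_spillover(synthetic_panel)
        for est in out.values():
            assert "neighbor_dry_t1" in est.params.index or True

    def test_constant_neighbor_column_warns_and_drops(self, synthetic_panel):
        panel = synthetic_panel.copy()
        panel["neighbor_dry_t1"] = 0.0
        with pytest.warns(UserWarning, match="neighbor_dry_t1"):
            out = fit_spillover(panel)
        for est in out.values():
            assert "neighbor_dry_t1" not in est.params.index
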