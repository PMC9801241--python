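"""Linear probability models of first internal migration.

The outcome is whether a person took their first internal migration trip
in year t; rows after the first trip leave the risk set.  Regressors are
lagged community weather categories (dry/wet/hot/cool relative to the
community's 1980-1990 baseline), individual, household and community
covariates, with state-by-year fixed effects absorbed and standard errors
clustered at the community level.

The fixed effects are absorbed by within-cell demeaning; coefficients are
identical (to numerical tolerance) to the dummy-variable fit.  The
default variance estimator is the CR2 (Bell--McCaffrey) clustered
sandwich, which rescales each cluster's residuals by
``(I - H_g)^(-1/2)`` to undo the downward bias of the plain clustered
estimator when clusters are few or unevenly levered; the CR1 estimator

    V = c * (X'X)^-1 [ sum_g (X_g' e_g)(X_g' e_g)' ] (X'X)^-1,
    c = G/(G-1) * (N-1)/(N-K),

with K counting the absorbed fixed-effect cells — exactly the
dummy-variable cluster-robust fit — is available via ``cr2=False``.
Predicted values are deliberately not clamped to [0, 1]: unbounded
predictions are a known property of the linear probability model and are
reported as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WEATHER_TERMS",
    "INDIVIDUAL_TERMS",
    "HOUSEHOLD_TERMS",
    "COMMUNITY_TERMS",
    "LPMEstimate",
    "build_panel",
    "build_design",
    "fit_lpm",
    "fit_heterogeneity",
    "fit_compounding",
    "fit_spillover",
]

#: reference levels: normal precip/temp, properties none, ag labor all,
#: internal-migration prevalence low
WEATHER_TERMS = ["dry_t1", "wet_t1", "hot_t1", "cool_t1"]
INDIVIDUAL_TERMS = ["age", "sex", "household_head", "education"]
HOUSEHOLD_TERMS = [
    "properties_medium",
    "properties_high",
    "ag_labor_some",
    "ag_labor_none",
    "prior_internal_migrants",
    "prior_us_migrants",
]
COMMUNITY_TERMS = [
    "share_men_agriculture",
    "internal_prev_medium",
    "internal_prev_high",
    "share_us_migration",
    "no_irrigation",
]


@dataclass
class LPMEstimate:
    """Coefficients and cluster-robust inference for one fitted model."""

    terms: pd.DataFrame  # columns: term, estimate, se, t, p
    n: int
    r2: float
    n_clusters: int
    n_cells: int
    outcome_degenerate: bool = False

    @property
    def params(self) -> pd.Series:
        return self.terms.set_index("term")["estimate"]

    @property
    def se(self) -> pd.Series:
        return self.terms.set_index("term")["se"]

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy import stats

        # t quantile with G-1 degrees of freedom, as for the p-values
        q = stats.t.ppf(0.5 + level / 2, max(self.n_clusters - 1, 1))
        lo = self.params - q * self.se
        hi = self.params + q * self.se
        return pd.DataFrame({"low": lo, "high": hi})

    def to_frame(self) -> pd.DataFrame:
        return self.terms.copy()


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

def build_panel(
    persons: pd.DataFrame,
    categories: pd.DataFrame,
    lags: set[int] | tuple[int, ...] = (1,),
    adjacency: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the person-year estimation panel.

    ``persons`` holds person-year rows (person_id, community_id, state_id,
    year, the binary outcome ``migrated`` and covariates); ``categories``
    holds community-year weather categories (and optionally a
    ``neighbor_dry`` column, or ``adjacency`` from which to build one).
    Rows after a person's first migration are dropped (risk set), and
    weather categories are joined at the requested lags as dummy columns
    against the *normal* reference.  Missing lagged weather raises with
    the offending community-years listed.
    """
    lags = set(lags)
    if not lags <= {1, 2}:
        raise ValueError("supported lags are {1} or {1, 2}")
    df = persons.sort_values(["person_id", "year"]).copy()

    # risk set: keep rows up to and including the first migration
    prior = df.groupby("person_id")["migrated"].transform(
        lambda s: s.shift(fill_value=0).cumsum()
    )
    df = df[prior == 0].copy()

    cats = categories.copy()
    if adjacency is not None and "neighbor_dry" not in cats.columns:
        from droughtmob.weather import add_neighbor_dry

        cats = add_neighbor_dry(cats, adjacency)

    keep = ["community_id", "year", "precip_category", "temp_category"]
    if "neighbor_dry" in cats.columns:
        keep.append("neighbor_dry")
    cats = cats[keep]

    for lag in sorted(lags):
        suff = f"_t{lag}"
        lagged = cats.rename(
            columns={
                "precip_category": "precip" + suff,
                "temp_category": "temp" + suff,
                "neighbor_dry": "neighbor_dry" + suff,
            }
        ).copy()
        lagged["year"] = lagged["year"] + lag
        df = df.merge(lagged, on=["community_id", "year"], how="left")
        missing = df["precip" + suff].isna()
        if missing.any():
            offenders = (
                df.loc[missing, ["community_id", "year"]]
                .drop_duplicates()
                .head(20)
                .to_records(index=False)
                .tolist()
            )
            raise ValueError(
                f"missing lag-{lag} weather for community-years: {offenders}"
            )
        df["dry" + suff] = (df["precip" + suff] == "dry").astype(float)
        df["wet" + suff] = (df["precip" + suff] == "wet").astype(float)
        df["hot" + suff] = (df["temp" + suff] == "hot").astype(float)
        df["cool" + suff] = (df["temp" + suff] == "cool").astype(float)
        if "neighbor_dry" + suff in df.columns:
            df["neighbor_dry" + suff] = df["neighbor_dry" + suff].astype(float)
    return df.reset_index(drop=True)


def build_design(
    panel: pd.DataFrame,
    include_controls: bool = True,
    extra_terms: list[str] | None = None,
) -> pd.DataFrame:
    """Named regressor matrix with categorical covariates expanded.

    Categorical covariates enter as dummies against their reference
    levels (properties: none; ag labor: all; internal prevalence: low).
    """
    out = pd.DataFrame(index=panel.index)
    for t in WEATHER_TERMS:
        out[t] = panel[t].astype(float)
    if include_controls:
        for t in INDIVIDUAL_TERMS:
            out[t] = panel[t].astype(float)
        out["properties_medium"] = (panel["properties"] == "medium").astype(float)
        out["properties_high"] = (panel["properties"] == "high").astype(float)
        out["ag_labor_some"] = (panel["ag_labor"] == "some").astype(float)
        out["ag_labor_none"] = (panel["ag_labor"] == "none").astype(float)
        out["prior_internal_migrants"] = panel["prior_internal_migrants"].astype(float)
        out["prior_us_migrants"] = panel["prior_us_migrants"].astype(float)
        out["share_men_agriculture"] = panel["share_men_agriculture"].astype(float)
        out["internal_prev_medium"] = (panel["internal_prevalence"] == "medium").astype(float)
        out["internal_prev_high"] = (panel["internal_prevalence"] == "high").astype(float)
        out["share_us_migration"] = panel["share_us_migration"].astype(float)
        out["no_irrigation"] = panel["no_irrigation"].astype(float)
    for t in extra_terms or []:
        out[t] = panel[t].astype(float)
    return out


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _demean_within(df: pd.DataFrame, cells: pd.Series) -> pd.DataFrame:
    return df - df.groupby(cells.to_numpy()).transform("mean")


def fit_lpm(
    panel: pd.DataFrame,
    regressors: pd.DataFrame | list[str],
    outcome: str = "migrated",
    fe: tuple[str, str] | None = ("state_id", "year"),
    cluster: str = "community_id",
    cr2: bool = True,
    drop_collinear: bool = False,
) -> LPMEstimate:
    """Least-squares fit of a binary outcome with absorbed fixed effects.

    ``regressors`` is a design frame (see :func:`build_design`) or a list
    of column names taken from the panel.  State-by-year cells are
    absorbed by demeaning; standard errors are clustered on ``cluster``
    with the CR1 small-sample factor (or CR2 when requested).  Rows with
    any missing value are dropped listwise with a warning.  A singular
    design raises, naming the collinear columns, unless
    ``drop_collinear`` asks for them to be removed with a warning
    (useful in small strata where community covariates collapse).
    """
    if isinstance(regressors, list):
        X = panel[regressors].astype(float).copy()
    else:
        X = regressors.astype(float).copy()
    y = panel[outcome].astype(float)

    mask = ~(X.isna().any(axis=1) | y.isna())
    dropped = int((~mask).sum())
    if dropped:
        warnings.warn(f"listwise deletion dropped {dropped} rows with missing values")
        X, y = X[mask], y[mask]
    panel = panel.loc[X.index]

    groups = panel[cluster]
    g_codes, g_uniques = pd.factorize(groups)
    G = len(g_uniques)
    if G < 2:
        raise ValueError("need at least 2 clusters for cluster-robust errors")

    if fe is not None:
        cells = panel[fe[0]].astype(str) + "\x1f" + panel[fe[1]].astype(str)
        n_cells = cells.nunique()
        Xd = _demean_within(X, cells).to_numpy()
        yd = _demean_within(y.to_frame("y"), cells)["y"].to_numpy()
    else:
        n_cells = 1  # global intercept
        Xd = (X - X.mean()).to_numpy()
        yd = (y - y.mean()).to_numpy()

    names = list(X.columns)
    N, k = Xd.shape
    degenerate = bool(np.allclose(y, y.iloc[0]))

    # collinearity diagnosis before solving
    rank = np.linalg.matrix_rank(Xd)
    if rank < k:
        # name offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(Xd, mode="economic", pivoting=True)
        bad = [names[i] for i in piv[rank:]]
        if not drop_collinear:
            raise np.linalg.LinAlgError(f"singular design; collinear columns: {bad}")
        warnings.warn(f"dropping collinear columns: {bad}")
        keep = [i for i in range(k) if names[i] not in bad]
        Xd = Xd[:, keep]
        names = [names[i] for i in keep]
        k = len(names)

    XtX = Xd.T @ Xd
    beta = np.linalg.solve(XtX, Xd.T @ yd)
    resid = yd - Xd @ beta

    K = k + n_cells
    XtX_inv = np.linalg.inv(XtX)
    order = np.argsort(g_codes, kind="stable")
    bounds = np.searchsorted(g_codes[order], np.arange(G + 1))
    if not cr2:
        meat = np.zeros((k, k))
        for g in range(G):
            idx = order[bounds[g] : bounds[g + 1]]
            s = Xd[idx].T @ resid[idx]
            meat += np.outer(s, s)
        c = (G / (G - 1)) * ((N - 1) / (N - K))
        V = c * XtX_inv @ meat @ XtX_inv
    else:
        # CR2: adjusted score s_g = X_g' (I - H_g)^{-1/2} e_g, computed in
        # the k-dimensional coefficient subspace: the non-unit action of
        # (I - H_g)^{-1/2} lives on the column space of X_g S^{1/2}
        evals, evecs = np.linalg.eigh(XtX_inv)
        S_half = (evecs * np.sqrt(np.maximum(evals, 0.0))) @ evecs.T
        meat = np.zeros((k, k))
        for g in range(G):
            idx = order[bounds[g] : bounds[g + 1]]
            Xg = Xd[idx]
            Xe = Xg.T @ resid[idx]
            Bg = S_half @ (Xg.T @ Xg) @ S_half
            lam, U = np.linalg.eigh(Bg)
            lam = np.clip(lam, 0.0, 1.0 - 1e-10)
            # f(lam) maps eigenvalues of H_g under (I - H_g)^{-1/2} - I
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(lam > 1e-12, (1.0 / np.sqrt(1.0 - lam) - 1.0) / lam, 0.5)
            adj = S_half @ (U * f) @ U.T @ S_half @ Xe
            s = Xe + (Xg.T @ Xg) @ adj
            meat += np.outer(s, s)
        V = XtX_inv @ meat @ XtX_inv

    se = np.sqrt(np.maximum(np.diag(V), 0.0))
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float((resid**2).sum())
    r2 = 0.0 if sst == 0 else 1.0 - ssr / sst

    from scipy import stats

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    dof = max(G - 1, 1)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    terms = pd.DataFrame(
        {"term": names, "estimate": beta, "se": se, "t": tvals, "p": pvals}
    )
    return LPMEstimate(
        terms=terms,
        n=int(N),
        r2=float(r2),
        n_clusters=int(G),
        n_cells=int(n_cells),
        outcome_degenerate=degenerate,
    )


def fit_heterogeneity(
    panel: pd.DataFrame,
    moderator: str,
    include_controls: bool = True,
) -> LPMEstimate:
    """Dry-weather effect interacted with a structural moderator.

    ``moderator`` is ``"properties"`` (household wealth proxy; dummies
    against the *none* reference) or ``"no_irrigation"`` (community has
    no irrigation).  The model keeps the full weather/control set.
    """
    panel = panel.copy()
    if moderator == "no_irrigation":
        if panel["no_irrigation"].nunique() < 2:
            raise ValueError("moderator no_irrigation is constant")
        panel["dry_x_no_irrigation"] = panel["dry_t1"] * panel["no_irrigation"]
        extra = ["dry_x_no_irrigation"]
    elif moderator == "properties":
        if panel["properties"].nunique() < 2:
            raise ValueError("moderator properties is constant")
        panel["dry_x_properties_medium"] = panel["dry_t1"] * (
            panel["properties"] == "medium"
        )
        panel["dry_x_properties_high"] = panel["dry_t1"] * (
            panel["properties"] == "high"
        )
        extra = ["dry_x_properties_medium", "dry_x_properties_high"]
    else:
        raise ValueError(f"unknown moderator {moderator!r}")
    X = build_design(panel, include_controls=include_controls, extra_terms=extra)
    return fit_lpm(panel, X)


def fit_compounding(
    panel: pd.DataFrame,
    stratify: str = "low_irrigation",
    include_controls: bool = True,
) -> dict[str, LPMEstimate]:
    """Joint lag-1/lag-2 dry effects by irrigation stratum.

    Requires the panel to carry lag-2 weather columns.  Returns one
    estimate per stratum (``low`` = under a fourth of cultivated land
    irrigated, ``high`` otherwise); a stratum with fewer than 2 clusters
    raises.
    """
    if "dry_t2" not in panel.columns:
        raise ValueError("panel lacks lag-2 weather; build it with lags={1, 2}")
    out = {}
    for label, sub in (("low", panel[panel[stratify] == 1]),
                       ("high", panel[panel[stratify] == 0])):
        if sub["community_id"].nunique() < 2:
            raise ValueError(f"stratum {label!r} has fewer than 2 clusters")
        X = build_design(sub, include_controls=include_controls, extra_terms=["dry_t2"])
        # no_irrigation is nearly collinear with the stratum; drop it
        X = X.drop(columns=["no_irrigation"], errors="ignore")
        out[label] = fit_lpm(sub, X, drop_collinear=True)
    return out


def fit_spillover(
    panel: pd.DataFrame,
    stratify: str = "low_irrigation",
    include_controls: bool = True,
) -> dict[str, LPMEstimate]:
    """Own vs neighboring-community dry-weather effects by stratum."""
    if "neighbor_dry_t1" not in panel.columns:
        raise ValueError("panel lacks neighbor_dry_t1; supply adjacency to build_panel")
    out = {}
    for label, sub in (("low", panel[panel[stratify] == 1]),
                       ("high", panel[panel[stratify] == 0])):
        if sub["community_id"].nunique() < 2:
            raise ValueError(f"stratum {label!r} has fewer than 2 clusters")
        extra = ["neighbor_dry_t1"]
        if sub["neighbor_dry_t1"].nunique() < 2:
            warnings.warn(
                f"neighbor_dry_t1 is constant in stratum {label!r}; column dropped"
            )
            extra = []
        X = build_design(sub, include_controls=include_controls, extra_terms=extra)
        X = X.drop(columns=["no_irrigation"], errors="ignore")
        out[label] = fit_lpm(sub, X, drop_collinear=True)
    return out
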