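# Methods

This note documents the models implemented in `droughtmob`, the
assumptions behind them, the default parameter choices, and what the
synthetic-data experiments do and do not establish.

## 1. Household livelihood ABM (Nepal-style community)

### Model

One community of 100 farming households is simulated over 2007–2035 at
two cropping cycles per calendar year (58 cycles).  Each household holds
a portfolio of livelihood strategies: exactly one farming strategy —
low-risk subsistence cereals or high-risk/high-reward cash crops — plus
optionally local migration (low entry cost, low remittance) and/or
overseas migration (high entry cost, higher remittance).  Households are
heterogeneous in risk aversion, starting wealth and (by scenario)
information access.

Each cycle proceeds in three steps.

**Perception.**  Households do not know the income distributions; they
estimate a mean and SD for each strategy.  The update is a convex blend:
weight 0.25 on the prior, 0.5 on reports pooled over the household
itself and its network neighbours (each report is the trailing 8-cycle
empirical mean/SD of that household's realised income from the
strategy), and 0.25 on a noisy government broadcast of the current true
parameters (mean noise SD 0.5).  Under *no* information access the
government term is dropped (weights renormalised to 0.5/0.5); under
*full* access perceptions equal the true current parameters every cycle.
Because drought cycles zero farming incomes, post-drought neighbour
reports depress the perceived farm mean and inflate the perceived farm
SD — this is the channel by which droughts raise the appeal of
income diversification.

**Decision (satisficing, then mean–variance choice).**  A household
keeps its portfolio unless its trailing 4-cycle mean income falls below
the median of its neighbours' trailing means, or below 0.9 × its own
previous trailing mean, or its wealth falls below a distress threshold
(1.5 cycles of subsistence consumption).  A dissatisfied household picks
the feasible portfolio maximising

    U(p) = mu_p − r · sigma_p

where `mu_p` sums perceived means net of recurring input costs,
`sigma_p` = sqrt of the summed perceived variances (strategy incomes
treated as independent), and `r` ≥ 0 is the household's risk aversion
(a variance penalty `mu − r·sigma²` is available via
`ModelParams.utility_form`).  Feasibility: recurring farm input costs
plus one-time entry costs of newly added migration strategies must not
exceed current wealth.  Ties break toward lower upfront cost, then the
fixed order subsistence < cash < local < overseas.  A distressed
household restricts its choice to portfolios containing local migration
whenever one is affordable — ex-post coping migration to meet basic
needs, a channel that operates even under full information, where the
perception channel is absent by construction.

**Income realisation.**  Incomes are drawn per strategy from gamma
distributions with the calibrated mean/SD (gamma rather than truncated
normal so that realised moments equal the specified ones — truncation
would otherwise bias perceived migration returns upward).  Droughts set
farming incomes to exactly zero for the affected cycles; warming scales
mean farm yields by `1 − 0.07·ΔT` (slope config-exposed); remittances
are unaffected by either.  Wealth updates as
`max(0, wealth + income − recurring costs − subsistence need)`.

**Migrant networks.**  The entry cost of a migration strategy falls with
migrant contacts: `cost = base · max(floor, 1 − m)`, where
`m = min(1, migrant_neighbours / 10)`.  Help from migrant contacts is
taken to saturate at ten ties: what matters for financing and
information is *how many* migrants a household can call on, not the
share of its acquaintances who migrated.  The floor differs by
destination: 0.2 for local moves, where a contact can supply most of
what a move needs (housing, a job lead), and 0.6 for overseas moves,
whose visas, flights and recruitment fees are an irreducible cash cost
no contact can waive.  The irreducible overseas cost is what lets a
drought's wealth shock constrain overseas uptake even in a maximally
connected community.  The saturation makes a degree-99 complete
network powerful at any prevalence, a sparse scale-free network
(average degree ≈ 4.5, preferential attachment with attachment count 2
or 3 with equal probability) heterogeneous — hubs get cheap migration
early — and a degree-1 "social isolation" network nearly
undiscounted.

**Climate forcing.**  Droughts arrive stochastically with a 1-in-20
annual probability during 2007–2020; thereafter only scenario-forced
droughts occur (both cycles of 2025 for a single shock; the four cycles
of 2024–2025 for consecutive shocks).  Trends: stationary, a linear
ramp to +1.5 °C at 2050, or a +1.5 °C spike in 2024 only.

### Calibration

Currency units are arbitrary (roughly thousands of NPR per cycle).  The
original survey calibration is not reproducible here, so the defaults
were set once to satisfy the qualitative structure of the published
experiment — local migration plateaus well before 2025 in a stationary
base case while overseas engagement keeps climbing through the
network-cost feedback, and a 2025 drought produces a local-migration
spike alongside a credit-constrained slowdown of overseas uptake:

| parameter | value | role |
|---|---|---|
| subsistence crop | cost 0, mean 10, SD 3 (recurring) | safe baseline; breaks even against the subsistence need |
| cash crop | cost 3, mean 14.5, SD 5 (recurring) | risky upgrade chosen by low-`r` households |
| local migration | entry 12, mean 1.0, SD 4 | low-reward diversification; affordable coping option |
| overseas migration | entry 100, mean 2.5, SD 9 | high-reward, wealth-gated; uptake rides the network discount |
| subsistence need | 10 per cycle | consumption floor; makes droughts deplete wealth |
| distress threshold | 1.5 × need | triggers coping migration |
| risk aversion | Gamma(2, 0.5) | heterogeneous thresholds straddling the adoption margins |
| starting wealth | LogNormal(ln 20, 0.8) | right-skewed; only the tail can finance overseas entry early |

Ensemble statistics use per-run seeds `base_seed + i`, so ensembles of
different scenarios with the same base seed are seed-paired; directional
comparisons use paired one-sided t-tests over per-run pre/post deltas
(two cycles after the forced window minus two cycles before, in
percentage points).  The drought-free base case is evaluated over the
same calendar window as the single-drought scenario.  Base-case
stability ("no net change by 2025–2026") is measured as the mean local
migration share over the 2026 cycles minus that over the 2025 cycles.

### What the ensembles show — and don't

Reproduced qualitatively and quantitatively (within ensemble spread):
the consecutive-drought local spike (~13–14 points), the ordering
consecutive > single, full network > single, full info < single, and
drought-suppressed overseas uptake relative to the base case.  The
single-drought spike runs larger than the published point value
(≈11–12 vs ≈7 points relative to base) — with the perception weights
fixed, the calibration could match either the single- or the
consecutive-drought magnitude exactly but not both; the consecutive
case was prioritised and the cross-scenario orderings are the binding
constraint.  Magnitudes are calibration-dependent throughout; only the
orderings should be read as model predictions.

## 2. Weather deviation and migration panel (Mexico-style)

### Season aggregation and classification

Daily community weather (rainfall, maximum temperature) is aggregated
over state-specific corn-season windows — June–February in Yucatán,
September–March in Baja California, Chihuahua, Nayarit, Sinaloa and
Sonora, May–December elsewhere; wrapped windows are indexed by their
ending calendar year.  Two season statistics: total rainfall, and the
longest run of consecutive days with tmax strictly above 30 °C.  Each is
standardised against the community's own 1980–1990 mean and SD; a
community-year is dry/wet (hot/cool) when |z| ≥ 1, with the boundary
classified into the extreme category.  A zero baseline SD raises rather
than classifying silently.  Neighbour exposure (`neighbor_dry`) is true
when any community adjacent in an input pair table is dry that year;
adjacency is an input precisely so a distance-based rule can be
substituted.

### Linear probability model

The outcome is first internal migration in a person-year risk set (rows
after a person's first migration are dropped).  Regressors: lagged
weather category dummies against the *normal* reference, individual
covariates (age, sex, household head, education), household covariates
(properties: ref *none*; agricultural labour: ref *all*; prior internal
and US migrants), and community covariates (share of men in
agriculture, internal-prevalence dummies: ref *low*; US-migration
share; no irrigation).  State-by-year fixed effects are absorbed by
within-cell demeaning; coefficients match the dummy-variable fit to
1e−8 (tested).  Inference clusters at the community level.  The default
variance estimator is CR2 (Bell–McCaffrey), which rescales each
cluster's residuals by `(I − H_g)^(−1/2)` to undo the downward bias of
the plain clustered sandwich when effective clusters are few or
unevenly levered — the dry × no-irrigation interaction, identified by
roughly 16 no-irrigation communities, is exactly that situation.  CR2
is computed in the k-dimensional coefficient subspace (eigenvalues of
`S^{1/2} X_g'X_g S^{1/2}`), so it costs little more than CR1 even with
hundreds of observations per cluster; it is verified against a dense
direct computation in the tests.  The CR1 estimator with small-sample
factor `G/(G−1)·(N−1)/(N−K)` (`K` counting absorbed cells) is
available via `cr2=False` and equals the dummy-variable
cluster-robust fit exactly.  Confidence intervals and p-values use the
t distribution with `G−1` degrees of freedom.  Predicted values are not clamped:
out-of-[0, 1] predictions are an acknowledged property of the linear
probability model.  Extensions: dry × household-properties and
dry × no-irrigation interactions; joint lag-1/lag-2 dry effects and
own-vs-neighbour dry effects, each stratified by whether under a
quarter of cultivated land is irrigated.  In small strata, collinear
community covariates are pruned with a warning (`drop_collinear`);
`fit_lpm` itself raises on a singular design, naming the offending
columns.

### Synthetic generators and what recovery shows

The weather generator draws a season total per community-year from a
normal law (CV 0.25 around a community mean near 600 mm) and spreads it
over season days by a Dirichlet-gamma split (shape 0.7 — many dry days,
few wet ones); daily tmax is an annual sinusoid (base ≈ 26 °C,
amplitude 6 °C) plus AR(1) noise (φ = 0.7, SD 2.5 °C), so multi-day
heat runs arise naturally.  About a sixth to a fifth of community-years
classify dry — the ±1 SD rule on near-Gaussian totals, inflated
slightly by 11-year baseline sampling noise, as with real baselines.

The panel generator plants known coefficients in the linear probability
(base rate 0.015 per person-year; planted dry, interaction, lag-2 and
neighbour effects configurable), with truncated state-year and
community-year shocks (SD 0.0015 each, truncated at ±2.5 SD to keep
probabilities in [0, 1]) inducing intra-cluster correlation.  Defaults
produce ≈50,000 person-years in 93 communities across 22 states —
scaled for desk-speed replication; the full survey scale is reachable
via `n_persons`.

Against this generator, the estimator recovers planted effects of the
published magnitudes (dry(t−1) ≈ 0.0024; dry × no-irrigation ≈ 0.0065)
without detectable bias over 200 replicates.  On a design with pure
intra-cluster error correlation and 93 clusters, the 95% cluster-robust
intervals cover at their nominal rate (tested).  On the full panel
design at the desk scale, however, measured coverage sits near 91%:
with ≈50,000 person-years the state-by-year cells hold only ~85
observations each, so the estimated cell means carry sampling noise
shared by the ~4 communities of a state, inducing a cross-community
score correlation that community-level clustering cannot absorb.  The
artifact shrinks with panel size (coverage ≈92–93% at the survey's
~437,000 person-years, where cells hold ~700 observations) and
disappears without fixed effects; clustering at the state level also
removes it, at the price of 22 rather than 93 clusters.  Community
clustering is retained as the analysis standard; the acceptance suite
reports the desk-scale coverage shortfall rather than hiding it.  As
always, recovery validates the estimation machinery, not the
substantive estimates: the generator satisfies the LPM's assumptions
by construction (no unmodelled confounding, no selective attrition,
categories measured without error), so recovery says nothing about
those threats in real survey data.

## 3. Numerical and reproducibility choices

* One `numpy` Generator per simulation run, seeded `base_seed + i`;
  initial wealth and risk aversion are drawn first so scenario pairs
  share them.
* Utility ties break at 1e−9 toward lower cost, then canonical strategy
  order — determinism under fixed seeds is tested byte-for-byte through
  the CLI manifest round trip.
* The vectorised community engine is cross-checked against the
  per-household operations by an exhaustive-argmax oracle on all
  ≤8-portfolio instances.
* Degenerate inputs raise rather than guess: infeasible degree
  sequences, forced droughts outside the horizon, zero baseline SDs,
  missing lagged weather (offenders listed), singular designs (columns
  named), strata with fewer than two clusters.

## 4. Known limitations

* The ABM community is closed (no in-migration, no household
  formation), destinations are binary local/overseas, and the household
  is the atomic agent.
* Strategy incomes are independent; real farm and local-labour incomes
  co-move with weather.  Remittances are drought-insensitive by
  assumption.
* The calibration is synthetic: levels (e.g. the share of households
  migrating) should not be compared to survey data, only the
  within-design contrasts.
* The weather generator has no spatial correlation between communities;
  neighbour-exposure effects in synthetic panels therefore come only
  from the planted coefficient, not from correlated weather.
* `migration_cost` uses a single floor parameter for both migration
  kinds; the contact-saturation count (10) is a modelling choice, not
  an estimate.
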