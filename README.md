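# droughtmob

Quantitative models of how compound drought events reshape human
mobility in smallholder farming communities, for researchers in
environmental demography and climate–society modelling.

Two complementary arms share the package:

* **A prospective agent-based model** of a 100-household farming
  community (Nepal-style) choosing livelihood portfolios — subsistence
  cereals, cash crops, local migration, overseas migration — under
  climate trends and drought shocks.  Households satisfice: they keep
  their portfolio unless income disappoints relative to their
  neighbours and their own aspiration, then re-optimise a mean–variance
  objective *U(p) = μ<sub>p</sub> − r·σ<sub>p</sub>* over affordable
  portfolios, with perceptions of each strategy's income distribution
  formed from social-network reports and a government signal, and
  migration entry costs falling with migrant contacts.  Eight
  experimental scenarios cross a warming trend, network topology,
  information access, and forced droughts in 2024–2025.

* **A retrospective weather-panel analysis** (Mexico-style): daily
  community weather is aggregated over state-specific corn seasons,
  standardised against each community's own 1980–1990 baseline
  (dry/wet, hot/cool at |z| ≥ 1), and linked to first internal
  migration in a person-year risk set through a linear probability
  model with state-by-year fixed effects and community-clustered
  standard errors — including dry × wealth and dry × irrigation
  heterogeneity, lag-1/lag-2 temporal compounding, and
  neighbouring-community spillovers.

Both arms are driven end-to-end by synthetic data generators
(`droughtmob.synth`) that emulate the survey and gridded-weather inputs
with known ground truth, so estimator bias and confidence-interval
coverage are measurable.  See `docs/methods.md` for the full model
description, parameter defaults and limitations.

## Worked example

Run a 200-simulation ensemble of the consecutive-droughts scenario and
summarise the pre/post-shock migration changes:

```python
from droughtmob import SCENARIOS, run_ensemble, migration_delta, StrategyKind

ens = run_ensemble(SCENARIOS["consecutive_droughts"], n_sims=200, base_seed=7)
deltas = migration_delta(ens)
for kind in (StrategyKind.LOCAL_MIGRATION, StrategyKind.OVERSEAS_MIGRATION):
    s = deltas[kind]
    print(f"{kind.value}: {s.mean:+.2f} pp (95% CI {s.ci_low:+.2f}..{s.ci_high:+.2f})")
```

```
local_migration: +13.28 pp (95% CI +12.35..+14.20)
overseas_migration: +1.90 pp (95% CI +1.60..+2.20)
```

Local migration jumps about 13 percentage points in the two cropping
cycles after back-to-back 2024–2025 droughts (ex-post coping plus
drought-inflated perceived farming risk), while overseas uptake grows
by under 2 points — less than in a drought-free base case over the same
window, because depleted wealth cannot cover the overseas entry cost.

The same pipeline is available from a shell:

```bash
droughtmob run --stage abm --scenario consecutive_droughts \
    --n-sims 200 --seed 7 --out results/
droughtmob summarize results/abm_results.csv --drought-cycles 34,35,36,37
```

Each run writes a `manifest.json` (config, seed, version, output
digests) from which it can be re-run byte-identically.

For the panel arm:

```python
from droughtmob.synth import WeatherGenSpec, PanelGenSpec, gen_daily_weather, gen_panel
from droughtmob.weather import aggregate_all_seasons, classify_panel
from droughtmob.lpm import build_design, fit_lpm

daily, communities = gen_daily_weather(WeatherGenSpec(seed=3))
seasons = aggregate_all_seasons(daily, dict(zip(communities.community_id, communities.state)))
cats = classify_panel(seasons)
panel = gen_panel(PanelGenSpec(seed=3), cats, communities)   # ~50,000 person-years
est = fit_lpm(panel, build_design(panel))                    # state×year FE, clustered SE
print(est.terms.head(4).to_string(index=False))
```

```
   term  estimate       se        t        p
 dry_t1  0.003475 0.001488 2.334714 0.021734
 wet_t1  0.000180 0.001646 0.109540 0.913013
 hot_t1  0.000018 0.001548 0.011954 0.990488
cool_t1  0.002423 0.001613 1.502213 0.136467
```

A dry corn season in the prior year raises the probability of a first
internal migration by about 35 basis points in this draw (the planted
default is 24 basis points; the estimate's clustered confidence
interval covers it), while wet, hot and cool deviations are
indistinguishable from zero.

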