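# densnest

Tools for analysing density-dependent breeding success in farmland
songbirds: territory-density metrics, Mayfield / logistic-exposure nest
survival, AICc model selection with multimodel averaging, mixed-model
R², and a demographic projection that turns productivity and survival
into annual population change. A configurable simulator generates
synthetic breeding-season datasets with known generative parameters so
every estimator can be checked for recovery.

## Scientific problem

Birds often settle at high density in habitat that looks good — tall,
continuous hedgerows — yet nests in those dense neighbourhoods can fail
more often, because shared nest predators (corvids) concentrate where
territories cluster. Whether preferred habitat is an ecological trap
hinges on a chain of quantities: how territory density responds to
boundary habitat, how daily nest survival responds to nearest-neighbour
distance (NND), how provisioning and nestling growth respond to
isolation, and what the resulting productivity implies for population
trend. This package implements each link of that chain.

## Models

- **Territory density** — counts per farm-year modelled as Poisson
  (log link) in log boundary lengths by habitat class, year and
  landscape, with farm random intercepts. Boundary segments are
  classified into six habitat classes (gappy hedge, hedge, hedge with
  10–50% or >50% tree canopy, vegetated fence, bare fence/wall). NND
  and NTND (mean distance to the three nearest neighbours) are capped
  at 1 km, within farm-year.
- **Nest survival** — visit histories reduce to exposure days
  (failed nests to the midpoint of last-active and first-failed
  visits), split into egg and nestling stages. Intercept-only fits
  reproduce the Mayfield estimator exactly; covariates enter through a
  logistic-exposure model (binomial with exposure days as trials,
  logit link on daily failure probability), optionally with random
  intercepts via a Laplace-approximated mixed model.
- **Model selection** — all admissible subsets of a global model
  (respecting marginality for interactions and quadratics), ranked by
  AICc; coefficients averaged over the ΔAICc < 2 top set with
  unconditional standard errors; marginal/conditional R² for mixed
  models, McFadden's R² for the ordinal fledgling-count model.
- **Demography** — successful nests per pair = renesting rate ×
  per-nest success; young per pair = that × young per successful nest;
  next year's adults = surviving adults + recruiting juveniles.

All estimators follow a statsmodels-style Model/Results layout:
construct a model object, call `.fit()`, read `params`, `bse`, `llf`,
`conf_int()`, `summary()` from the results.

## Worked example

Demographic projection from measured rates (1.66 nesting attempts per
pair, 45% per-nest success, adult survival 0.449, juvenile survival
0.440, 2.42 young per successful nest):

```python
>>> from densnest import DemographicParams, project
>>> res = project(DemographicParams(
...     renest_rate=1.66, nest_success=0.45,
...     young_per_successful_nest=2.42,
...     adult_survival=0.449, juvenile_survival=0.440))
>>> print(res.summary())
n_pairs                      100.000
successful_nests_per_pair      0.747
young_total                  180.800
adults_next_year             169.300
annual_change_pct            -15.300
dtype: float64
```

With 3.19 young per successful nest the same projection gives 238.3
young per 100 pairs and an annual change of −2.7%.

Logistic-exposure survival on a toy dataset (2 failures over 51
exposure days; the intercept-only fit is exactly the Mayfield
estimator, daily survival 49/51 ≈ 0.9608):

```python
>>> import numpy as np
>>> from densnest import LogisticExposure, mayfield_dsr
>>> f = np.array([1., 0., 0., 1., 0.])          # failure indicators
>>> t = np.array([10.5, 12., 9., 4.5, 15.])     # exposure days
>>> mayfield_dsr(f.sum(), t.sum())
(0.9607843137254902, 0.027180520787594982)
>>> LogisticExposure(f, t, np.ones((5, 1))).fit().summary()
    estimate        se  lower_ci  upper_ci
x0 -3.198673  0.721393 -4.612578 -1.784768
```

A full configured run (simulate a season, compute density metrics and
exposure summaries, dredge seven analyses, project demography):

```bash
densnest run --out demo_run
```

takes ~15 s and writes, among others, `demo_run/nestling_failure_averaged.csv`:

```text
term,n_models,estimate,se,lower_ci,upper_ci,significant
Intercept,2,-1.5585614873812061,0.28840427104987115,-2.1238338586389536,-0.9932891161234587,True
nnd,2,-0.006456720520216266,0.0012191251629830484,-0.00884620583966304,-0.004067235200769491,True
concealment,1,0.06621863161806396,0.12317002800865229,-0.1751946232788945,0.30763188651502243,False
```

The averaged NND coefficient (−0.0065 ± 0.0012) recovers the
simulator's generative nestling-stage slope of −0.007 on the logit
scale: nests further from their neighbours fail less. The
`demography.csv` table in the same run reproduces the projection above
for both productivity scenarios.

Other subcommands: `densnest simulate`, `densnest density`,
`densnest survival`, `densnest dredge`, `densnest demography`
(see `densnest --help`).

## Reproduction

All computations are deterministic given a seed. To regenerate the
headline quantities as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Re-running any pipeline config with the same seed reproduces
byte-identical output tables; `run_log.txt` records the config hash.
`docs/methods.md` documents the statistical methods, numerical choices
and the simulator's scope.
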