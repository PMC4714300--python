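# kdepi

Comparative epidemiology of Kawasaki disease (KD) and paediatric infectious
diseases from age-binned sentinel surveillance: force-of-infection mapping,
the catalytic susceptibility model, seasonality, wavelet-based super-annual
periodicity, and spatial regression of regional differences on
climatic/socioeconomic covariates.

## The problem

KD is assumed to be infectious but its aetiological agent is unknown. If KD
behaves like an endemic immunizing infection, its surveillance record can be
interrogated with the standard machinery of infectious-disease epidemiology
and compared, disease by disease, with infections whose agents are known:

* **Force of infection.** For an acute immunizing infection at endemic
  equilibrium the per-susceptible infection hazard is approximately the
  inverse of the mean patient age, `λ = 1/A`. `A` is estimated from
  age-binned case counts as the case-weighted mean of age-group midpoints,
  crude (`cA`) or directly age-standardized to a standard population
  structure (`aA`), regionally and nationally.
* **Catalytic model.** With constant `λ`, the fraction of a birth cohort
  still naive at age `t` is `V(t) = exp(−t/A)` with `V(0) = 1`. Combining
  `1 − V(t)` with the cumulative risk of an actual diagnosis by age `t`
  yields `P(disease | infection)`.
* **Super-annual periodicity.** Endemic immunizing infections cycle with
  inter-epidemic period `T = 2π√(A·(D + D′))`, where `D` is the incubation
  and `D′` the infectious period. The dominant multi-year cycle of a monthly
  case series is measured with a Morlet continuous wavelet transform
  (cone-of-influence and red-noise significance included); the relation can
  be inverted to bound `D + D′` from an observed `T`.
* **Geography.** Regional (adjusted) mean ages are screened against
  covariates by Spearman rank correlation, triaged for collinearity by
  factor-analysis uniqueness, selected by stepwise OLS, and finally fitted
  with the spatial-lag model `Y = ρUY + Xβ + e` (maximum likelihood, binary
  contiguity matrix `U`) to account for spatial autocorrelation.

Real national KD surveillance and sentinel-clinic records are not
redistributable, so the package ships a synthetic generator
(`kdepi.synthetic_data`): a seasonally forced stochastic SEIR metapopulation
with demographic turnover, fertility-driven regional birth rates, reporting
thinning, and recorded ground truth — every stage of the analysis runs at
desk scale against known answers.

## Worked example

```bash
python examples/catalytic_chain.py
```

```
force of infection lambda = 1/A = 0.4167 per year
by age 3: infected 71%  diagnosed 0.7%  P(KD | infection) ~ 1%
by age 5: infected 88%  diagnosed 0.9%  P(KD | infection) ~ 1%
=> nearly all children meet the agent early, but only about one infection
   in a hundred manifests as Kawasaki disease.
```

With a mean patient age of 2.4 years, 71% of children have met the agent by
age 3 and 88% by age 5; yet only 0.7%/0.9% carry a KD diagnosis by those
ages, so roughly 1% of infections manifest clinically — the agent must
circulate widely and almost always silently.

The other scripts in `examples/` each exercise one capability and print a
one-line interpretation: `mean_age_and_foi.py` (FOI recovery from binned
ages), `seasonality_profile.py` (bimodal school-term profile),
`wavelet_periodicity.py` (measured vs predicted inter-epidemic period, and
the inversion giving `D + D′ ≈ 1.1` y for KD from `T = 10` y at `A = 2.4`
y), `spatial_regression_demo.py` (recovery of `ρ = 0.4`), and
`full_demo.py` (the whole pipeline on synthetic surveillance, FOI recovery
correlation ≈ 0.99).

## Layout

```
src/kdepi/
  data_model.py          tables, CSV I/O, weekly->monthly, max-normalization
  synthetic_data.py      SEIR generator, exponential ages, regression fixtures
  mean_age.py            crude / adjusted / national mean patient age
  foi_catalytic.py       lambda = 1/A, V(t), diagnosis risk, manifestation
  seasonality.py         monthly profiles, peak-structure classification
  periodicity.py         Morlet CWT, COI, red-noise significance, T relation
  spatial_regression.py  screening, uniqueness, stepwise OLS, spatial lag ML
  pipeline.py            configuration and the end-to-end runner / demo
examples/                one narrative script per capability
docs/methods.md          models, assumptions, numerical choices, limitations
```
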