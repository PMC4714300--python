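# Methods

This note records the models implemented in `kdepi`, the assumptions they
rest on, the defaults and why, and what the synthetic data generator does
and does not emulate.

## Mean patient age and the force of infection

Case counts `N_ijkm` (disease `i`, region `j`, age group `k`, year `m`) are
pooled over the study years — by default every year present in the table;
an eleven-year window is typical, long enough to average over seasonal
variation in patient age. The crude mean patient age is the case-weighted
mean of the age-group midpoints `M_k`. The default age-group scheme has 11
paediatric bins (0–<0.5, 0.5–<1, yearly to 9, 9–<15 years) with midpoints
computed from the bounds; the scheme is fully configurable because only the
bounds and midpoints enter any formula.

The adjusted mean removes demographic interference by direct
age-standardization: age-specific rates `N_ijkm / C_jkm` (cases over the
region-year population share of the group) are reweighted by a standard
structure `S_k`:

    w_k  = S_k * sum_m N_ijkm / C_jkm
    aA   = sum_k M_k w_k / sum_k w_k

When `C == S` this is exactly the crude mean (tested to 1e-12). A region
with cases in a group whose population share is zero is an error, never a
silent drop. National values pool counts over regions; the national
adjusted mean standardizes against the across-region pooled structure,
population-weighted when region populations are available, with a
sensitivity variant (`pooling="averaged"`) that case-weights the regional
adjusted means instead.

`λ = 1/A` is the endemic-equilibrium approximation for an acute immunizing
infection under Type I (fixed-longevity) survival, appropriate for a
low-mortality population. Binning introduces a small upward bias in `A`
(midpoints overstate the within-bin mean of a decaying age distribution);
with the default scheme and `A ≈ 2.4` y the bias is under 1%, well inside
the sampling tolerance of the recovery tests.

## Catalytic susceptibility model

`V'(t) = −λV`, `V(0) = 1`, so `V(t) = exp(−t/A)`. The cumulative diagnosis
risk by age `t` is the average annual case count under age `t` divided by
the average annual birth cohort; the default denominator is uncorrected for
child mortality (a survival-corrected variant is available — at the
mortality levels this analysis targets the correction is far below the
reporting precision). The manifestation probability is the ratio of the
diagnosis risk to `1 − V(t)`. Report output carries raw and rounded forms;
rounding (integer percent, or one decimal for the diagnosis risk) is purely
presentational.

## Seasonality

For each complete calendar year the share of that year's cases falling in
each month is computed from raw monthly counts (no per-day normalization —
month lengths are left as the surveillance convention has them); the
profile is the across-year mean and standard deviation, optionally ordered
April-first to follow the school year. Years with zero annual totals are
excluded with a logged warning. Peak structure is read from circular local
maxima with prominence at least a configurable fraction of annual cases
(default 0.01); "major" versus "minor" peaks is inherently judgment-based,
so the threshold is exposed rather than hidden.

## Wavelet periodicity

Monthly series are max-normalized, mean-removed and linearly detrended,
then transformed with the Morlet wavelet (`ω₀ = 6`) on a dyadic scale grid
(10 sub-octaves per octave, smallest scale 2 months), following the
standard Torrence–Compo conventions: cone of influence from the `√2·s`
e-folding rule, pointwise 95% significance against a fitted lag-1
autoregressive (red-noise) background via the chi-square(2) test, and a
COI-masked global spectrum tested with time-averaged degrees of freedom.
At least 48 monthly points are required; super-annual inference on anything
shorter is refused rather than degraded.

The dominant super-annual period is the COI-masked global-spectrum maximum
over periods above a floor, subject to significance. Two choices matter:

* **Search floor.** The function default is 12 months; the pipeline and the
  summary report search above 18 months so that scale-domain leakage of the
  seasonal (annual) line is not mistaken for a super-annual cycle.
* **Family-wise control.** The maximum is taken over many correlated
  scales, so the per-scale red-noise test is Šidák-corrected for the
  effective number of independent scales (about one per 0.6 octave for the
  Morlet wavelet). On featureless noise the measured false-detection rate
  is ~10% — above the nominal 5% because the chi-square approximation is
  loose at the small degrees of freedom of long periods — and "none
  detected" is a first-class outcome, since the absence of detectable
  super-annual periodicity is itself the scientifically meaningful result
  for some diseases.

The inter-epidemic period relation `T = 2π√(A(D+D′))` is isolated in
`predict_T` / `invert_T` so the functional form can be swapped in one
place. Its round-trip is exact; its empirical validity is checked against
stochastic SEIR simulations (measured dominant period within 20% of the
prediction across a sweep of `A` and `D+D′`).

## Spatial regression

Screening retains a covariate only when its Spearman rank correlation with
the (adjusted) mean patient age is significant for **every** disease at
`α = 0.05`; constant covariates are reported as not retained with a reason.
Collinearity triage uses iterated principal-axis factoring on the
correlation matrix (factor count by the eigenvalue>1 rule, communalities
initialized at squared multiple correlations); uniqueness = 1 −
communality, flagged below 0.4 by default (the cut is judgment-based and
configurable). Stepwise selection alternates forward addition (smallest
P < 0.05) and backward elimination (P > 0.10), deterministic with ties
broken by smaller P then covariate name; forced covariates (e.g. a vaccine
uptake rate) bypass screening but face elimination like any other.

The spatial-lag model `Y = ρUY + Xβ + e` is fitted by maximum likelihood:
`ln|I − ρU|` from the eigenvalues of `U`, `ρ` profiled out by bounded
scalar optimization strictly inside the invertibility interval
`(1/λ_min, 1/λ_max)`, `β` by generalized least squares at `ρ̂`, and
standard errors from the numerical Hessian of the full likelihood. `U` is
used raw binary by default, matching a contiguity definition; a
row-standardization flag is provided, and parameter-recovery experiments
use the row-standardized grid because only there does `ρ = 0.4` lie inside
the invertibility interval of a 47-region contiguity grid. An all-zero `U`
degrades to OLS with `ρ̂ = 0` and a warning; the zero-adjacency fit equals
OLS to 1e-8.

## Synthetic surveillance generator

`simulate_seir` runs a daily Euler-binomial SEIR per region: infection
totals are binomial draws against `λ_j(t) = β_j(t)·I_j/N_j + import`,
latency and recovery are binomial exits, and susceptibles live in
real-valued monthly age cohorts (0–40 y) depleted proportionally, which
fixes the age distribution of infections without a full age-structured
model. Seasonal forcing is `β(t) = β₀(1 + ε·term(t))` with a sinusoidal or
April-start school-calendar square-wave term. Births enter the youngest
cohort continuously; everyone ages out at the tracking horizon (Type I
survival). Reported weekly and yearly age-binned counts are binomial
thinnings at the reporting fraction, drawn from a stream separate from the
dynamics so changing the reporting fraction does not perturb the epidemic
trajectory at a fixed seed. Extinction is flagged in the bundle, never
silently resimulated. The exported demography is computed from the
simulator's own cohort structure, so `C_jkm` is consistent with the cases.

Default conditions mirror the study design: 47 regions, an eleven-year
recording window starting in 2000, weekly reporting, and regional birth
rates proportional to a fertility (TFR) covariate — the sibling-contact
mechanism by which fertility drives the force of infection
(`λ*_j ≈ birth rate_j × R0_j`). Per-region population defaults to 3×10⁵
and the demo uses 2×10⁵ with a small external import hazard (10⁻³/year per
susceptible): desk-scale sizes chosen so that endemic persistence is
typical while a full multi-disease, 47-region demo completes in seconds.
The acceptance-level period-law sweep uses a single region at 5×10⁵ over a
40-year record, where the demographic-noise-excited inter-epidemic cycle is
measured cleanly.

What the generator does **not** emulate: sentinel-clinic allocation bias,
age-dependent contact or hazard, maternal-immunity windows, multi-strain
dynamics, true spatial transmission coupling (regions are independent given
their parameters — the spatial-lag recovery therefore uses the dedicated
regression fixture with explicit `ρ`), and reporting artefacts such as
holiday closures. Passing tests demonstrate estimator correctness under the
model's own assumptions, not robustness to these real-data features.

Parameter-recovery experiment sizes are package choices: 200 replicates for
the spatial-lag and screening simulations; the `ρ = 0` centering check uses
fixtures with `β = (2, 1)` and unit noise (R² ≈ 0.8, comparable to the
regional regressions this emulates) so that the bound on mean |ρ̂| reflects
estimator centering rather than an arbitrarily weak signal.

## Numerical conventions and degenerate inputs

* Week-to-month conversion apportions each week's count across months by
  day count (n/7 rationals), conserving totals exactly; overlapping or
  duplicate weeks are errors.
* Max-normalization requires a positive maximum; all-zero series are
  errors. Normalization is idempotent.
* Mean ages are undefined (error) at zero total cases; adjusted means name
  the offending (region, age group, year) when a populated share is zero.
* All tables are keyed by explicit string identifiers; the adjacency matrix
  carries its region ordering and is validated symmetric, binary,
  zero-diagonal.
* One configured seed is expanded into logged per-stage child seeds
  (all below 2³¹); same seed plus same config reruns bit-identically.

## Known limitations

`λ = 1/A` presumes endemic equilibrium and lifelong immunity; it is biased
during epidemic transients (the generator shows mean infection age falling
below `1/λ` in small, strongly oscillating populations). The uniqueness
rule and the stepwise thresholds are conventions, not inference; the
spatial-lag standard errors are asymptotic. The wavelet family-wise
false-detection rate is approximate (see above). Eleven-year series leave
little cone-of-influence room above ~4-year periods, so long super-annual
cycles are detectable only as "none detected at this length" — which is
exactly how the longest-period diseases present in this framework.
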