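# Methods

`coldstun` implements an analysis chain for annual sea-turtle cold-stun
stranding counts: derive candidate climate covariates from a daily
sea-surface-temperature (SST) series, locate the climate time window that
best explains the counts, screen candidates by permutation importance, fit
a Bayesian negative-binomial regression that carries covariate measurement
error, and forecast future counts under a linear warming extrapolation.
This note records the models, the defaults and why, and the design choices
made where the design was genuinely open.

## Data model

The response is the yearly count of cold-stunned Kemp's ridley turtles
found in a stranding season (October–January, labelled by its starting
year).  Candidate predictors are per-year summaries of daily regional-mean
SST, monthly NAO/AMO climate indices, and the number of hatchlings released
on the Mexican index beaches 2–4 years earlier (the cohort ages of the
juveniles that strand).  Daily SST carries a per-day measurement SD, as
satellite-interpolation products publish; missing days are never imputed —
window statistics fail loudly instead, because silently filling gaps biases
window minima.

## Climate time windows

A window is a contiguous span of days before a 31 December reference,
written as day offsets `(open, close)`, `open ≥ close ≥ 0`.  Six aggregate
statistics summarize the daily SSTs inside a window: mean, maximum,
minimum, sample SD (n−1), days with daily mean < 10 °C (the cold-stun
onset temperature — strict inequality, "below" read literally) and days
with daily mean > 20 °C.

Every window on the grid is scored by the small-sample-corrected AIC
(AICc) of a Gaussian linear model of `log(count + 1)` on the windowed
statistic; the best window is the exact exhaustive minimizer.  Defaults:

| parameter | default | rationale |
|---|---|---|
| reference date | 31 Dec of the stranding year | end of the season |
| `max_open` | 365 days | spans windows from midsummer through December |
| `min_length` | 14 days | half-month resolution floor |
| scoring model | Gaussian on log(count+1) | fast, monotone-equivalent for ranking strong signals; an NB-GLM scorer would rank the same strong candidates at ~50× the cost |
| criterion | AICc (k = 3) | n = 35 is small; plain AIC differs only by a constant shift per k |

Ties (within 1e−9) break toward the shorter window, then the later close.
Selected windows are reported as half-month labels: days 1–14 of a month
are its "early" half, day 15 onward "late".

## Permutation importance and the two-stage screen

"Mean decrease in accuracy" is computed the standard way for regression
forests: each of `n_trees` (default 2,000; ~500 is already stable for this
problem size) trees is grown on a bootstrap sample with ⌈p/3⌉ predictors
tried per split; for each predictor, its values are permuted among the
tree's out-of-bag rows and the rise in out-of-bag squared error, averaged
over trees, is the importance.  The forest is assembled from
`DecisionTreeRegressor` trees with an explicit bootstrap so the out-of-bag
rows of every tree are known; the whole procedure is deterministic given
its seed.

The default candidate table holds 11 predictors: the six SST statistics,
each at its own best window; the June–September NAO sum; the annual-mean
NAO lagged 2 years; the annual-mean AMO; the mean of the AMO at lags 1–3
(collapsed into one column to keep the candidate set compact); and the
lag-2/3/4 hatchling average.  Stage 1 ranks all candidates; groups of SST
summaries with pairwise |r| ≥ 0.7 (a common collinearity rule of thumb;
configurable) are collapsed to their best-ranked member; stage 2 re-ranks
the survivors and its top two go forward to the count model.  Non-SST
candidates are never eliminated by the collinearity screen.

## The errors-in-variables count model

    y_t ~ NegBin(mu_t, k),        Var = mu + mu²/k
    log mu_t = beta_0 + Σ_j beta_j z_jt
    x_jt ~ Normal(z_jt, s_jt²)    (s_jt known)

The SST covariate uses a *heteroscedastic* error structure: one SD per
year, the window-mean of the per-day SDs (≈ 0.19 °C).  The hatchling
covariate uses a *homoscedastic* structure: a single SD equal to the
sample SD of the final 10 release years, where the trend has asymptoted,
so the residual year-to-year scatter there proxies the series' measurement
error.

Covariates are standardized internally; posteriors are reported on both
scales (the original scale is the standardized slope divided by the sample
SD — exact, not approximate).  Priors are vague but proper and
configurable: Normal(0, 10²) on standardized coefficients, Gamma(2, rate
0.1) on k, Normal(0, 10²) on standardized latent values.  The latent prior
is deliberately weak so the measurement model dominates.

### Sampling

The posterior is sampled by adaptive Metropolis-within-Gibbs MCMC.  Given
the coefficients and dispersion, the latent covariate values of different
years are conditionally independent, so all n latents update in a single
vectorized per-year Metropolis sweep; each coefficient and log k update as
scalar blocks.  Proposal scales adapt toward the 0.44 scalar acceptance
target during burn-in only (Roberts–Rosenthal style), then freeze, leaving
a valid fixed-kernel chain.  Four independent chains run by default
(6,000 iterations, 2,000 burn-in, ~4,000 stored draws); convergence
requires split-chain R-hat < 1.01 and bulk ESS > 400 on every reported
parameter, else the fit raises (configurable to warn).  Replicate
simulation studies use a reduced preset (2,200 iterations, 800 burn-in)
whose calibration the test suite verifies directly.

### Diagnostics and selection

* **DIC** = D̄ + pD with pD = D̄ − D(θ̄); the deviance is *conditional* on
  the latent covariates (DIC variants differ — the conditional form is
  the common default of latent-Gaussian software and is stated here
  because marginalized variants give different absolute values).
* **Overdispersion statistic**: Σ r_t²/(n − p) with Pearson residuals
  r_t = (y_t − μ̂_t)/√(μ̂_t + μ̂_t²/k̂) at posterior means; ≈ 1 for an
  adequate likelihood.
* **Residual ACF** of Pearson residuals, for screening leftover temporal
  structure.  (Latent AR(1)/random-walk trend terms are deliberately out
  of scope; the ACF is the diagnostic offered instead.)
* **Backward selection**: a covariate is removed when removal lowers DIC,
  or when its 95% interval spans zero with a standardized posterior mean
  below 0.1 in magnitude; every candidate model's DIC, including the
  intercept-only baseline, is tabled.

## Forecasting

The recent SST trend is OLS on the last 15 yearly values of the windowed
minimum, parameterized through the mean point of those years (slope and
intercept-at-mean are then mutually consistent).  The line is extrapolated
15 years; each projected value carries a fixed 0.5 °C error SD — the
projection is itself uncertain, and this SD feeds the same measurement
channel the model was fitted with.  Forecasts are posterior predictive:
per posterior draw, perturb the projected SST, map through the log link
and draw a fresh NB count, so intervals carry parameter, covariate and
count-level uncertainty (fitted-mean-only bands would be far too narrow
for count data).

The population-impact figure divides the summed published female
abundances at ages 2–4 (Gallaway et al. 2016: 32,060 + 23,057 + 22,918)
by the mean of the published female sex ratios (0.65 in-situ, 0.74
protected) to estimate total age-2–4 juveniles, then expresses a predicted
count as a percentage of that total.  A 2,349-count event is ≈ 2.09% of
the ≈ 112,281 estimated juveniles under this arithmetic.

## Synthetic data: what it emulates, and what it does not

The generator plants known ground truth so every stage is testable:

* Daily SST = annual mean (11 °C) + linear warming (0.03 °C/yr) + seasonal
  sinusoid (amplitude 8 °C, maximum in early August so the late-October
  window sits on the cooling limb) + AR(1) noise (stationary SD 0.8 °C,
  φ = 0.7 — daily SSTs are strongly autocorrelated, and window minima are
  sensitive to this).  Per-day error SDs are truncated-normal around
  0.19 ± 0.02 °C.  The series starts one year before the first season so
  the full search grid is covered.
* Hatchlings follow a logistic trend (capacity 6×10⁵, rate 0.18/yr,
  midpoint 2000) with lognormal noise, asymptoting over the final decade.
* Counts are NB draws with log-mean β₀ + β₁x_t + β₂h_t, defaults
  β₀ = −8.7, β₁ = 1.2 per °C of the windowed SST minimum (days 77–47
  before 31 Dec, i.e. 15 Oct–14 Nov), β₂ = 0, k = 3 — 35 seasons whose
  counts range from single digits to a few hundred, like the observed
  series.
* Measurement error is applied to the *windowed statistic* (one value per
  year), matching how the count model consumes error; the per-day SDs are
  aggregated by their window mean.  The daily series itself is the truth.
* Simple AR(1) monthly NAO/AMO series are generated so the full
  11-predictor table can be assembled.

Not emulated: spatial SST structure, hurricanes and other episodic
forcing, observer-effort changes, and any real teleconnection between the
climate indices and the counts.  Passing tests therefore demonstrate that
the *methods* recover planted structure at the study's n and noise levels —
not that the real ocean behaves like the generator.

The packaged example tables (`s1_strandings_synthetic.csv`,
`s2_hatchlings_synthetic.csv`) are synthetic stand-ins constrained to the
documented facts of the real record (35 seasons 1982–2016; the 1,188-count
2014 season; only 1999 and 2002 above 100 before 2009; a saturating
release trend 1966–2018).

## Problem sizes used by the test suite

Simulation studies use the replicate counts their questions need: 50 seeds
for window recovery and importance ranking, 100 reduced-length MCMC
replicates for interval calibration, 50 paired fits for the attenuation
property.  Heavy loops run forests at 500 trees (stable at this problem
size) and windows on reduced grids where the question does not require the
full-year grid; package defaults remain 2,000 trees and the full grid.
The window-recovery study plants the window *mean* with dispersion k = 10:
the mean uses every day of the window, making window placement sharply
identifiable, whereas a planted minimum is mostly determined by the days
nearest the close, so shorter overlapping sub-windows score equally well
and "recovery" becomes ill-defined rather than hard.  The importance study
likewise runs at k = 10: at k = 3 the six window-optimized SST summaries
are near-interchangeable proxies of the same warming signal, and which one
tops a ranking is close to arbitrary — the check is that the machinery
identifies the driver when the data distinguish one, not that it breaks a
genuine statistical tie.

## Known limitations

* With large measurement error and a vague latent prior, the EIV fit
  widens intervals and lifts |β| relative to the naive fit but does not
  fully de-attenuate; a hierarchical latent-mean model would, at the cost
  of extra assumptions.
* DIC with conditional deviance under-penalizes latent-heavy models;
  comparisons here are between models sharing the same latent structure.
* The Gaussian log-count window scorer can prefer slightly shifted windows
  when counts are heavily overdispersed; it is configurable in principle
  to an NB-GLM scorer at much higher cost.
* The forecast extrapolates a 15-year linear trend and holds the
  population assumptions fixed; both are acknowledged simplifications, not
  climate projections.
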