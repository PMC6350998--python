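# coldstun

Climate-window covariates and errors-in-variables count models for
sea-turtle cold-stun stranding series.

Juvenile sea turtles foraging at the cold edge of their range become
hypothermic ("cold-stunned") when autumn water temperatures drop before
they migrate south; annual counts of stranded cold-stunned Kemp's ridleys
in Cape Cod Bay have climbed from single digits in the 1980s to hundreds —
over 1,100 in 2014.  `coldstun` is for quantitative ecologists asking the
questions that series raises: *which* climate summary, over *which* span
of days, best explains the counts; whether population growth or ocean
warming is the driver; and what the counts look like if the warming trend
continues.

## The model

The pipeline's core is a Bayesian negative-binomial regression whose
covariates are measured with known error:

```
y_t ~ NegBin(μ_t, k),          Var(y_t) = μ_t + μ_t²/k
log μ_t = β₀ + Σⱼ βⱼ z_jt
x_jt ~ Normal(z_jt, s_jt²)     — observed covariate, known error SD
```

The SST covariate (the minimum of daily mean sea-surface temperature over
a data-selected window before the stranding season) carries a
heteroscedastic error structure — one SD per year, from the satellite
product's per-day error fields (≈ 0.19 °C).  The hatchlings-released
covariate carries a homoscedastic SD derived from the asymptoting tail of
its own series.  Ignoring such error attenuates slopes toward zero;
modelling it keeps the covariate signal honest.

Around that core: exhaustive AICc sliding-window search for each of six
aggregate SST statistics (mean, max, min, SD, days < 10 °C, days > 20 °C);
out-of-bag permutation importance from a bootstrap regression forest with
a two-stage collinearity screen; backward model selection by DIC with
overdispersion and residual-ACF diagnostics; and posterior-predictive
forecasting of counts under a linear SST extrapolation.  A synthetic-data
generator with known ground truth (seasonal cycle, warming trend, AR(1)
daily noise, planted climate window and effect sizes) makes the whole
chain testable end to end.  See `docs/methods.md` for the full model and
design notes.

## Worked example

```python
import pandas as pd
import coldstun as cs

params = cs.ScenarioParams(seed=1)          # 35 seasons, planted SST-min driver
sc = cs.make_scenario(params)

win = cs.best_window(sc.strandings, sc.sst, "min")
print(f"best window for SST minimum: {win.half_month_label} "
      f"(days {win.best.open}-{win.best.close} before 31 Dec), "
      f"AICc {win.ic_best:.1f} vs null {win.ic_null:.1f}")

spec = cs.ModelSpec(
    covariates=("sst_min",),
    error={"sst_min": cs.MeasurementErrorSpec("heteroscedastic", sc.truth.err_sd)},
)
X = pd.DataFrame({"sst_min": sc.truth.x_obs})
fit = cs.fit_nb_eiv(spec, sc.strandings, X, seed=7)
print(fit.summary.loc[["beta_sst_min_orig", "k"]].round(2))
print(f"overdispersion: {cs.overdispersion_stat(fit):.2f}")

trend = cs.fit_sst_trend(sc.strandings.years, sc.truth.x_obs, last_n=15)
proj = cs.project_sst(trend, start_year=2017, horizon=15)
fc = cs.predict_counts(fit, proj, seed=11)
last = fc.table.iloc[-1]
print(f"2031 predictive mean {last.count_mean:.0f} "
      f"[{last.count_q025:.0f}, {last.count_q975:.0f}]")
print(f"impact of a 2,349-count event: "
      f"{cs.population_impact(cs.PopulationAssumptions(), 2349):.2f}% of juveniles")
```

prints

```
best window for SST minimum: early May thru early November (days 244-47 before 31 Dec), AICc -36.0 vs null 9.9
                   mean  q025  q975
beta_sst_min_orig  1.10  0.85  1.37
k                  4.48  2.19  8.17
overdispersion: 0.91
2031 predictive mean 63 [8, 217]
impact of a 2,349-count event: 2.09% of juveniles
```

Reading it: the window search lands on a span whose close sits in early
November, covering the planted mid-October–mid-November window (the long
open tail is typical for a *minimum* statistic — on the cooling limb the
minimum is set by the days nearest the close).  The posterior slope 1.10
[0.85, 1.37] per °C covers the planted truth 1.2; the dispersion k ≈ 4.5
and an overdispersion statistic near 1 say the NB likelihood is adequate.
The forecast propagates the fitted warming trend and full posterior — the
wide interval is count-level, not mean-level, uncertainty.  The last line
applies the published age-2–4 abundance and sex-ratio estimates to a
2,349-count event: about 2% of the juvenile population.

The `coldstun` CLI wraps the same stages
(`coldstun all --config config.yaml --seed 1`); packaged synthetic
stand-ins for the stranding-count and hatchling tables ship with the
package (see `coldstun.packaged_strandings_path()`).

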