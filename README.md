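# salgrowth

Hierarchical Bayesian analysis of stream-salamander growth under timber
harvest, built around capture–mark–recapture (CMR) data from a
before–after control–impact (BACI) design: one unharvested control stream
and two streams whose surrounding stands were clear-cut (January 2015 and
January 2016) with riparian buffers retained. The question: did harvest
change individual growth rates of the Ouachita dusky salamander
(*Desmognathus brimleyorum*)?

The package is organised as an analysis project: every computation lives
in the library under `src/salgrowth/`, and the numbered scripts under
`analysis/` drive the pipeline and write tables and figures under
`results/`. A synthetic-data generator emulates the field study's design,
so the entire pipeline runs and is tested without the field dataset.

## The model

Growth is observed as recapture increments. For interval *i* with start
length *X* (mm), elapsed time *T* (days) and length change *Z* (mm), the
Wang parameterization of the Fabens method gives

```
Z = (l∞ + β(X − E(X)) − X) (1 − e^(−kT)) + ε,    ε ~ Normal(0, σ)
```

where `l∞ + β(X − E(X))` is a first-order approximation to the
individual's asymptotic length (β absorbs asymptote heterogeneity) and
*k* is the growth coefficient (day⁻¹). Harvest acts on log *k* with site
and year random intercepts truncated to ±2:

```
log(k_i) = α₀ + α·harvest_i + η_site[i] + η_year[i]
η_site ~ Normal(0, σ_site),  η_year ~ Normal(0, σ_year),  |η| ≤ 2
```

`exp(α)` is the multiplicative effect of harvest on growth rate — the
headline quantity. Priors: uniform(0, 0.1) on the baseline k, Normal(0, 10)
on α, Normal(0, 1) on β, uniform(0, 100) on l∞, exponential(1) on all
standard deviations. Intervals that straddle a site's harvest date carry a
Bernoulli(0.5)-prior missing harvest state; intervals spanning several
calendar years mix the year effect uniformly over the years spanned. Both
discrete latents are marginalized analytically in the default likelihood
(an explicit-latent Gibbs mode is available). Sampling is by a seeded
adaptive-Metropolis MCMC with ridge-following translation and scaling
moves; convergence is monitored with the Gelman–Rubin statistic
(threshold 1.03). Model fit is assessed with a sum-of-squares posterior
predictive Bayesian p-value. Two ancillary analyses accompany the model:
June metamorph size comparisons per site-year, and a body-condition
one-way ANOVA on ranked residuals of log(mass) ~ log(SVL) (gravid females
excluded).

## Worked example

```
$ python analysis/01_simulate_study.py --seed 1
captures           : 2936
individuals marked : 1523
recaptured >=1x    : 785
recapture events   : 1413

$ python analysis/02_build_intervals.py
growth intervals     : 989
mean start SVL (mm)  : 40.06
missing harvest state: 173
negative increments  : 59

$ python analysis/03_fit_growth_model.py --seed 1
...
growth-rate ratio exp(alpha): 1.40 (95% CrI 1.26-1.71)
Pr(harvest effect > 0)      : 1.00

$ python analysis/04_posterior_check.py --seed 1
Bayesian p-value (sum of squares): 0.545 over 1000 draws
model adequate

$ python analysis/05_body_size.py
post-minus-pre June metamorph size at BA1: +5.0 mm
post-minus-pre June metamorph size at BA2: +6.6 mm
body condition: F(1,2925) = 2.43, p = 0.119 (regression R^2 = 0.97, n = 2927)
```

Reading this: the generator planted a true 1.4-fold post-harvest growth
effect, and the fitted posterior centers the growth-rate ratio on 1.40
with the credible interval excluding 1 — the harvest effect is recovered.
The Bayesian p-value near 0.5 says replicated datasets are no more and no
less discrepant than the observed one, i.e. the model fits. Negative
increments are expected (measurement error on animals near their
asymptote) and the Gaussian residual absorbs them. The 173
missing-harvest intervals straddle a harvest date and are marginalized,
not discarded. The body-condition test is null here because the generator
ties mass to length identically in both groups.

`03_fit_growth_model.py --paper-scale` runs 5 chains of 1.2M iterations
(burn-in 200k, thinning 50) instead of the desk-scale default of 4×20k.

## Layout

```
src/salgrowth/
  io_cmr.py     capture/site CSV readers, 21-day filter, interval builder
  model.py      increment equation, priors, marginalized likelihood
  mcmc.py       adaptive Metropolis sampler, R-hat, posterior summaries
  ppc.py        posterior predictive check (sum-of-squares Bayesian p)
  body_size.py  metamorph size summaries, ranked-residual condition ANOVA
  simulate.py   synthetic CMR study generator and recovery experiments
  report.py     figures and run manifests
analysis/       numbered pipeline drivers (simulate → ... → body size)
scripts/        acceptance.py (full from-scratch reproduction)
docs/methods.md model, assumptions, numerical choices, limitations
```
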