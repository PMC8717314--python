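# Methods

## The growth model

The observation unit is a recapture pair of one marked salamander: start
snout–vent length X (mm), elapsed time T (days), and length change Z
(mm). Classical Fabens fitting of the von Bertalanffy curve to increments
assumes a common asymptote; with heterogeneous asymptotes that assumption
biases the growth coefficient. The Wang correction replaces the common
asymptote by a first-order approximation `l∞ + β(X − E(X))` that lets an
individual's apparent asymptote co-vary with its observed size, with E(X)
the sample mean start length. The mean increment is therefore

    E[Z] = (l∞ + β(X − E(X)) − X)(1 − e^(−kT))

and the residual ε ~ Normal(0, σ_resid) absorbs both process and
measurement error with a single constant SD. One typographical note: the
increment equation is often typeset without brackets; the grouping above
is the only one under which `l∞ + β(X − E(X))` is an asymptote multiplying
the Fabens saturation factor, and it is what this package implements. A
consequence worth knowing: the expected increment is strictly decreasing
in X (for β < 1) and crosses zero at X₀ = (l∞ − β·E(X))/(1 − β), the
"zero-growth length"; animals larger than X₀ are expected to shrink on
paper, which is measurement error doing its job, so negative observed
increments are retained.

The growth coefficient varies on the log scale:

    log(k_i) = α₀ + α·harvest_i + η_site[i] + η_year[i]

with harvest a 0/1 indicator (0 = control or pre-harvest, 1 =
post-harvest), and site and year random intercepts drawn from zero-mean
Gaussians truncated to [−2, 2] — with only three sites and three years the
truncation keeps poorly informed levels from wandering, and e² ≈ 7.4 means
a level may still move the growth rate sevenfold either way. The
truncation is implemented as a renormalized density, not post-hoc
clamping; clamping would put point masses at ±2 and bias the SD estimates.

Time is measured in days and k in day⁻¹; the uniform(0, 0.1) prior is
placed on the baseline coefficient exp(α₀) (control conditions, random
effects at zero) and induces the prior on α₀ by change of variables.
Remaining priors: Normal(0, 10) on α, Normal(0, 1) on β, uniform(0, 100)
on l∞ (mm), exponential(1) on every SD — all deliberately vague at the
scale of the data.

### Discrete latents

Two kinds of interval carry a discrete unknown. An interval that starts
before and ends after its site's harvest date has an undefined harvest
state; it receives a Bernoulli(0.5) prior and the likelihood becomes an
equal-weight two-component mixture. An interval spanning several calendar
years has its year effect assigned by an equal-probability categorical
draw over the years spanned (not time-weighted averaging). The default
likelihood marginalizes both analytically — a small Gaussian mixture per
interval — which any continuous-parameter sampler can use; an
explicit-latent mode (`mode='latent'`) instead carries the assignments
and Gibbs-resamples them each sweep, reproducing the formulation a
BUGS/JAGS program would use. The two are distributionally identical; a
test checks their posterior summaries agree.

Harvest-date conventions at day precision: a capture on the harvest date
counts as post-harvest; the missing state requires strict straddling
(start < harvest < end), so an interval ending exactly on the harvest
date is pre-harvest (all its growth occurred before the cut).

## Sampling

The posterior is sampled with an adaptive random-walk Metropolis chain
over (l∞, β, α₀, α, η's, log σ's), with the log-σ Jacobians folded into
the target. Three move types run each sweep:

* a global Gaussian proposal whose covariance is learned during burn-in
  (equal-weight Haario adaptation; Robbins–Monro step-size tuning toward
  23% acceptance; both frozen at the end of burn-in so the retained chain
  is Markovian);
* translation moves along the additive non-identifiability between α₀ and
  each random-effect block (the likelihood sees only their sum; only the
  priors resist the slide, so these moves mix the ridge cheaply);
* a scaling move trading amplitude against rate (k scaled by e^δ while
  l∞ − E(X) and β − 1 shrink by e^(−δ), with the appropriate Jacobian),
  which follows the curved ridge the saturation factor creates when most
  intervals have kT ≪ 1.

Defaults are desk-scale — 4 chains × 20,000 sweeps, burn-in 5,000,
thinning 5 — which fits the simulation studies in the test suite on one
CPU; `MCMCConfig.paper_scale()` gives 5 chains × 1.2M (burn-in 200k, thin
50) for long production runs. The acceptance script uses an intermediate
4 × 60,000 for its single headline fit. Convergence is assessed per
parameter with the Gelman–Rubin statistic in its classic between/within
form, floored at 1 and compared against a 1.03 threshold; non-convergence
is flagged on the result object and warned about, never silently dropped.
The σ posteriors have long right tails under the exponential(1) prior with
only three levels (credible intervals reaching past 2 are normal), and
their R-hat is the last to settle at desk scale. All chains are
deterministic given the seed; chain seeds are spawned from a single
`SeedSequence`.

Initial states are drawn overdispersed within the prior support (l∞ in
45–75 mm, baseline k in 8×10⁻⁴–10⁻², etc.), re-drawn up to 100 times if
an initialization lands at zero density (truncation corners).

## Posterior predictive check

For each retained draw the discrete latents are sampled from their
conditional posterior given the observed increments — they are model
unknowns, so this is exactly the state a Gibbs sampler carrying them
would hold — giving expected increments μ. The observed discrepancy is
Σ(z_obs − μ)² and the replicated discrepancy Σ(z_rep − μ)² with z_rep ~
Normal(μ, σ_resid), and the Bayesian p-value is the fraction of draws
with D_rep ≥ D_obs (ties counted). Raw, not standardized, residuals enter
the sums; with a constant residual SD the two differ only by a factor.
Conditioning the latents on the data matters: drawing them from their
priors instead depresses p to ~0.17 on data generated from the model
itself, while the conditional version is calibrated (p ≈ 0.49 on
average). Sum-of-squares discrepancies with a fitted variance are known
to concentrate near 0.5 rather than distribute uniformly — useful as a
misfit alarm (a tenfold variance inflation drives p to 0), weak as a
goodness-of-fit certificate. The standalone `replicate_increments`
operation, meant for generating fresh datasets rather than checking fit,
draws latents from their priors.

## Body-size analyses

Metamorph sizes: June captures at most 45 mm SVL (recently metamorphosed
animals) summarized per site-year (n, mean, quartiles), with each
treatment site's shift reported as mean(post-harvest) − mean(pre-harvest)
pooled over years. Body condition: ordinary least squares of log(mass) on
log(SVL) pooled over all included captures, residuals ranked (average
ranks on ties), one-way ANOVA of ranks between the control group
(control-site plus pre-harvest captures) and the treatment group
(post-harvest captures at treatment sites). Ranking makes the test
invariant to monotone transforms of the residuals; the natural log is
used on both axes (the base cancels). Gravid females are excluded by
default — clutch mass inflates condition — but only from this analysis;
their growth intervals stay in the growth model, since length is not
affected the way mass is. Degrees of freedom are reported as (groups − 1,
n − groups) alongside n itself, since published F statistics sometimes
count denominator df differently.

## The synthetic-data generator

`simulate_intervals` draws increments directly from the model's
generative assumptions on a fixed interval design — the exact-recovery
workhorse — while `simulate_cmr_study` emulates the field study end to
end: three sites (control; BA1 harvested 15 Jan 2015; BA2 harvested 15
Jan 2016, entering the survey a year late), March/June/October surveys
with three nights per month (days 7/14/21) over 2014–2016, June metamorph
recruitment with initial SVL ~ Normal(25, 3) truncated to 20–30 mm, an
initial standing cohort per site, individual latent trajectories
dL/dt = k_i(a_i − L) with per-individual asymptotes a_i ~ Normal(l∞, 4.5)
and k switching at the harvest date and at year boundaries, constant
monthly survival, nightly detection, and Normal(0, 1 mm) measurement
error on recorded lengths. Mass follows log(mass) = −10.7 + 3·log(SVL) +
Normal(0, 0.12) (≈3.9 g at 56 mm), with optional post-harvest condition
shifts and a gravid-female mass bump.

Default true values are the study's conditions: l∞ = 60.3 mm, baseline
k = 0.002/day (a 25 mm June metamorph reaches ≈43 mm a year later,
matching the species' juvenile trajectory), harvest ratio
exp(α) = 1.4, σ_site = 0.35, σ_year = 0.46, metamorph post-harvest size
shifts +5.7 mm (BA1) and +4.0 mm (BA2), no condition shift. Detection
(0.15/night), monthly survival (0.92) and recruitment (230 per
site-year + 150 initial per site) were chosen once so the simulated study
marks ≈1,500 individuals with ≈800 recaptured — the field study's scale —
and are knobs of the emulation, not estimates.

What the emulator deliberately does not reproduce: spatial structure and
movement along the transect, temperature- or prey-driven growth
mechanisms, size- or state-dependent detection and survival, larval
dynamics beyond the initial metamorph size, and — importantly — the
field data's size–asymptote coupling. In the emulator an individual's
asymptote is independent of its recruitment size, so the fitted β (which
measures how apparent asymptote tracks observed size) comes out small
(~0.1) and the zero-growth length sits close to l∞ rather than well above
it. Recovery tests therefore check that asymptote heterogeneity is
detected (β > 0), not that β matches any particular value: β is an
approximation device, not a simulable quantity. Passing tests show the
estimation machinery is correct under the model's own assumptions, not
that the model is adequate for any particular field system.

Interval-level recovery experiments use a randomized BACI design: 600
intervals spread over 3 sites × 3 years, start lengths ~ Normal(45, 8)
clipped to 25–70 mm, gaps of 40–200 days, ~12% two-year spans, and
straddling (missing-harvest) intervals concentrated in each treatment
site's harvest year.

## Data-processing rules

Captures fewer than 21 days apart carry no growth signal at measurement
resolution. The filter retains captures greedily per individual in date
order — keep the first; keep each later capture only if ≥21 days after
the last kept — then pairs successive retained captures into intervals.
Greedy retention is deterministic and maximizes usable intervals; the
count identity Σ(retained − 1) = #intervals holds by construction.
Negative increments are kept. Individuals with fewer than two retained
captures contribute nothing (not an error). Both recapture-count
interpretations (recapture events; total captures of recaptured animals)
are countable from the built dataset, since published tallies are
ambiguous between them.

## Numerical notes

* Mixture likelihoods are evaluated with segment-wise logsumexp
  (`reduceat` over per-interval component blocks); the sampler's inlined
  target is pinned to the reference log-posterior by a unit test at
  10⁻¹⁰ relative tolerance.
* `expm1` is used for 1 − e^(−kT) to keep tiny increments accurate.
* Truncated-normal densities renormalize with erf; log-σ proposals beyond
  e^±30 are treated as out of support rather than risking under/overflow.
* Quantile summaries use pooled post-burn-in draws; the growth-rate
  ratio's quantiles are exp of the α quantiles (monotone transforms
  commute with quantiles; interpolated sample quantiles would disagree in
  the 8th decimal), while its mean is the mean of the exponentiated
  draws.
* β = 1 makes the zero-growth length undefined (every animal grows
  forever); it is raised as a degenerate-input error.
* Ties in the PPC comparison (D_rep = D_obs) count as ≥, the
  conventional choice.

## Known limitations

* The sampler is random-walk Metropolis; posterior tails of the σ
  parameters mix slowly at desk scale (flagged by R-hat, remedied by the
  longer configurations).
* A single constant σ_resid conflates process and measurement error;
  the generator's measurement error is homoscedastic to match.
* The condition ANOVA pools control and pre-harvest captures into one
  group, as the BACI contrast requires; site-level pseudo-replication is
  not modelled.
* Sex effects on growth are not modelled (field sexing of the species is
  unreliable without dissection), and no occupancy, abundance or survival
  modelling is attempted.
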