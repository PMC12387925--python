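# Methods

## Model

Death times are modelled as exponentiated Weibull,
F(t) = [1 − exp(−(t/σ)^θ)]^α with exponentiation shape α > 0, Weibull
shape θ > 0 and scale σ > 0 (days). This is the Mudholkar–Srivastava
parameterisation; at α = 1 it collapses to the Weibull and at α = θ = 1 to
the exponential, identities the test suite asserts for all five
distribution functions. The scale carries the regression:
σᵢ = exp(xᵢ·β), where xᵢ treatment-codes categorical cohort covariates
(treatment arm, sex, age group) against explicit reference levels
(uninfected, male, youngest age) with optional pairwise interactions. The
shapes are shared across cohorts within a fit.

Daily death counts are interval observations; we treat a death recorded on
day d as an exact event at the interval midpoint t = d − 0.5. This keeps
the likelihood closed-form, avoids a zero-density boundary at d = 1, and
approximates the interval-censored likelihood well at day resolution
relative to scales of tens of days (the generator's ceiling binning plus
this midpoint rule introduces a bias that the recovery tests bound: with
2000 flies per arm all 95% intervals still cover the generating values).
A full interval-censored likelihood is out of scope. The likelihood is
count-weighted — Σ deaths·log f(d − 0.5; α, θ, σᵢ) over distinct
(covariates, day) records — which is exactly the per-individual expansion
(tested). Cohorts are followed to extinction, so there is no censoring
term.

Biological and technical replicates are pooled within a population type:
replicate identity is kept in the table schema but carries no model term,
matching population-level analysis; random cage effects are a noted
limitation. Fits are intended per (population type, age at spray) with
treatment × sex covariates; a pooled all-ages fit with age-group factors
is equally supported by the same machinery. Control arms describe handling
effects and are best summarised in a separate descriptive fit; the
immunity contrast uses the infected and uninfected arms only.

## Priors

The analysis this package supports specifies Bayesian estimation but no
particular prior family, so the defaults are our own weakly informative
choice, stated and overridable: βⱼ ~ Normal(0, 10²) on the log-scale link
(covering scale ratios over many orders of magnitude) and α, θ ~
Half-Normal(0, 5²) (proper, positive support, diffuse over every hazard
shape the family offers). `PriorSpec(flat=True)` removes the prior terms
for likelihood-only checks.

## Sampler

No conditional conjugacy exists, so "Gibbs plus Metropolis–Hastings" is
realised as Metropolis-within-Gibbs: random-walk Gaussian proposals cycle
over blocks — log α, log θ, then the coefficients either coordinate-wise
(default; better mixing when coefficients correlate weakly) or as one
joint block. Sampling the shapes on the log scale keeps proposals in the
support; the log-transform Jacobian is added to the target. Proposal
scales adapt toward 0.3 acceptance during burn-in only (multiplicative
updates every 100 iterations), so the retained chain is a fixed-kernel
Markov chain; acceptance rates are reported per block and land in
(0.05, 0.95) on all tested problems. Initialisation is a method-of-moments
Weibull fit (α started at 1, θ and the intercept from the weighted
mean/CV of death days, remaining coefficients 0), which is cheap and
always inside the support; a non-finite initial target raises an explicit
initialisation error.

Chain schedule: the desk-scale default is 40,000 draws, 10,000 burn-in,
thinning of 10 — 3,000 retained draws. This is a scaled-down version of a
production schedule of 800,000–1,000,000 draws with 200,000–300,000
burn-in and thinning of 200–250 (`MCMCConfig.production_scale()`), both
respecting the ≥ 2,000 retained-draw floor; the scaled schedule keeps
each fit to a few seconds so that twenty-replicate recovery studies run
in minutes on one core. Retention is floor((n_draws − burn_in)/thin),
tested at off-by-one boundaries. Single-chain lag-k autocorrelation (via
statsmodels) is the convergence diagnostic, mirroring a thin-after-ACF
workflow; multi-chain R-hat is deliberately out of scope.

## Posterior summaries

All summaries are per-draw transforms reduced to the posterior median and
an equal-tailed 95% percentile interval (the point estimate is the median
by design choice; the reduction is configurable in code). The immunity
statistic (σ_inf − σ_unif)/σ_unif is reported as a magnitude — infection
shortens life, making the raw value negative, while the convention in this
literature prints positive values — and the signed per-draw summary is
retained alongside, so no information is discarded. It is scale-free
(invariant to multiplying all σ draws by a constant, tested) and, for
profiles differing only in treatment, reduces to |exp(δ) − 1| with δ the
treatment coefficient.

Hazard ratios are time-resolved because the exponentiated Weibull is not
proportional-hazards for α ≠ 1; the default evaluation grid is the
observed day range, and the acceptance script's scalar convenience value
is evaluated at the uninfected posterior-median survival-halving time —
an explicit convention, since a single per-age HR can equally be an
average or a fixed-time value. In the Weibull reduction the F/M ratio is
constant and equals (σ_F/σ_M)^(−θ), which the tests assert exactly. The
median residual lifetime is closed-form, S⁻¹(S(t₀)/2) − t₀ via the
quantile function, checked against bisection to 1e−6.

## Synthetic cohorts

The generator emulates the design of a spray-infection assay: two
population types (short-/long-lived), four biological × two technical
replicates, age-at-spray ladders of {14, 28, 42} and {14, 28, 42, 56, 70}
days, both sexes, three arms (infected/uninfected/control), cage sizes
uniform on 100–150, daily mortality to extinction. Death times are drawn
by inversion and binned by ceiling (observed at the first daily check).
Defaults are synthetic, not calibrated to any real cohort (no raw cohort
data is distributed with the motivating study): long-lived reference
scale 48 days vs short-lived 28, α = 1.5, θ = 2.2, infection effect −0.10
on log σ deepening with age via interactions, female effect +0.06, age
effects −0.15·(age rung). An untreated age-14 arm and the 24 h
germination period exist in the schema as labels only — no quantitative
handle for them exists. What passing recovery tests show is therefore
internal validity (the pipeline recovers truths generated under its own
model family, including the day-binning mismatch); they cannot certify
behaviour under cage effects, model misspecification, or censoring, none
of which the generator produces.

## Overlap test

The multi-set intersection test draws each set independently and
uniformly without replacement with fixed sizes from a shared background —
the standard exact null. The total-intersection distribution is built by
a forward recursion (conditional on the running intersection size j,
intersecting the next set of size n_k is hypergeometric Hyp(N, j, n_k)),
linear in the number of sets; the two-set case is the hypergeometric
upper tail exactly, and three-set tails are verified against 10⁶-draw
Monte Carlo enumeration. The background size is a required user input:
results are meaningless without stating the universe. The acceptance
script uses 17,700, an approximate count of annotated genes in the
r5-era *D. melanogaster* reference annotation, for its worked example on
published list sizes.

## Numerical choices

log-densities use expm1/log1p forms; t = 0 densities take their analytic
limits (0, αθ/σ or ∞ as αθ ⋛ 1). Nonpositive shapes or scales yield −inf
from the likelihood (rejection) rather than exceptions; constructor-level
validation raises. Quantiles and MRL are closed-form (no root-finding in
the implementation; bisection appears only as a test oracle with 1e−6
agreement). Credible intervals use linear-interpolation quantiles.
Zero-variance chains raise a degenerate-chain error from the ACF check
instead of propagating NaN. Problem sizes in the test suite (2,000 flies
per arm, twenty seeds, 40k-draw chains) were chosen so the full recovery
study reflects the statistical regime of a real assay while completing in
minutes.

## Known limitations

Single-chain diagnostics only; no frailty/random effects for cages or
replicates; no interval-censored likelihood; midpoint/ceiling day handling
biases shape estimates slightly at coarse day resolution relative to the
scale; the immunity magnitude convention folds the (rare) posterior mass
with σ_inf > σ_unif onto the positive axis; the overlap null assumes
exchangeable genes (no length or LD structure).
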