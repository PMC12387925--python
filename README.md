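# ewsurv

Bayesian exponentiated-Weibull survival regression for cohort mortality
data, written for experimental-evolution and infection-assay studies in
which caged *Drosophila* (or similar) cohorts are followed with daily death
counts until every individual has died. It quantifies **immune defense** as
the relative compression of the survival curve caused by infection, and
ships a synthetic cohort generator plus an exact multi-set gene-list
intersection test for the genomic side of such studies.

## The model

Time to death follows the exponentiated Weibull distribution

    F(t) = [1 − exp(−(t/σ)^θ)]^α,     α, θ, σ > 0,

whose two shape parameters admit unimodal and bathtub hazards. Cohort
covariates (treatment arm, sex, age at spray, interactions) act on the
scale through a log-linear link, σᵢ = exp(xᵢ·β), so the model is an
accelerated-failure-time-style regression. The posterior over (α, θ, β) is
sampled by adaptive Metropolis-within-Gibbs (random-walk blocks on log α,
log θ and the coefficients), with burn-in, an autocorrelation check and
thinning; every reported summary is a function of the retained draws:

- **Immunity percent change** |σ_infected − σ_uninfected| / σ_uninfected —
  smaller means the infection compressed survival less, i.e. stronger
  immune defense.
- **Hazard ratios** h_A(t)/h_B(t) (male baseline by convention: HR > 1
  means the baseline group survives better).
- **Median residual lifetime** at t₀: the time until half of those alive at
  t₀ have died, S(t₀ + MRL) = S(t₀)/2.
- **Survival curves** with pointwise 95% credible bands.

The overlap module computes the exact null distribution of the
intersection size of m fixed-size sets drawn independently from a common
background, by a forward recursion linear in m (the two-set case is the
hypergeometric tail).

## Worked example

```python
from ewsurv import ExpWeibullSurvivalRegression, simulate_two_arm

# 2000 flies per arm; infection multiplies the true scale by exp(-0.105) ≈ 0.90
table = simulate_two_arm(2000, alpha=1.5, theta=2.0, sigma_uninfected=20.0,
                         treatment_effect=-0.105, seed=1)

est = ExpWeibullSurvivalRegression(factors=("treatment",), seed=1).fit(table)
imm = est.immunity({"treatment": "infected"}, {"treatment": "uninfected"})
print(round(imm.estimate, 3), tuple(round(v, 3) for v in imm.ci))
print(est.median_residual_lifetime({"treatment": "uninfected"}, [0.0]))
```

prints

```
0.106 (0.082, 0.128)
    t0     median         lo         hi
0  0.0  19.914584  19.503016  20.309417
```

The immunity estimate 0.106 (95% CI 0.082–0.128) recovers the true 10%
scale compression; the uninfected cohort's median lifetime is ~19.9 days
against a closed-form truth of 19.9. The same workflow is available from
the shell (`ewsurv simulate`, `ewsurv fit`, `ewsurv summarize`,
`ewsurv overlap`), each command writing CSV outputs with a `.meta.json`
sidecar recording the seed and config hash.

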