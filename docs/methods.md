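# Methods

## The modelling problem

Screening totals such as the MoCA and VCAT are sums of item scores bounded
at 30, with early-stage cohorts concentrated near the ceiling.  Treating the
total as normal misrepresents both tails: predicted values are symmetric
around the mean and can exceed the maximum or go negative.  `skewfit`
compares two remedies jointly: (a) replacing the normal with skew-capable
families, and (b) modelling the inverse score `30 − s` — the number of
errors — which is a right-skewed non-negative count, the home ground of
count and positive-continuous distributions.  The transform is a linear
involution, so it loses nothing and its coefficients read directly as
effects on the error count.

## Families and parameterisations

All families share a linear predictor `eta = X beta` (intercept first; sex
coded female = 1; age and education in years, untransformed).  Links and
auxiliary parameters:

| family    | link target            | auxiliary          | admissible       |
|-----------|------------------------|--------------------|------------------|
| normal    | mean (identity)        | sigma              | sigma > 0        |
| lognormal | log-scale location     | sigma (log scale)  | sigma > 0        |
| gamma     | mean (log)             | shape a            | a > 0            |
| weibull   | scale (log)            | shape k            | k > 0            |
| poisson   | mean (log)             | —                  |                  |
| nb (NB2)  | mean (log)             | alpha; var μ(1+αμ) | alpha ≥ 0        |
| cmp       | rate lambda (log)      | nu                 | nu > 0           |
| gp        | mean (log), θ = μ(1−δ) | delta              | 0 ≤ delta < 1    |

Notes on the non-obvious choices:

* **CMP** is parameterised by (λ, ν) with covariates on log λ because the
  mean-parameterised CMP has no closed form; CMP coefficients are therefore
  *not* log-mean effects and are not comparable across families.  The
  normalising constant `Z(λ, ν) = Σ λ^j/(j!)^ν` is summed in log space
  starting past the term peak at `j* = λ^{1/ν}`, extending until the current
  term falls below `tol` (default 1e-12) times the running sum, with a hard
  cap of 10,000 terms; exceeding the cap raises a numerical error naming
  (λ, ν) rather than returning a truncated value.
* **GP** uses Consul's form `P(y) = θ(θ+δy)^{y−1}e^{−(θ+δy)}/y!` restricted
  to the overdispersed branch `0 ≤ δ < 1` (mean μ = θ/(1−δ), variance
  μ/(1−δ)²).  The negative-δ branch truncates the support and is omitted —
  a documented limitation; inverse screening scores are overdispersed in
  practice.  Sampling is exact via the branching representation (Poisson(θ)
  ancestors, Poisson(δ) offspring; the total progeny is GP).
* **NB2**'s `lgamma(y+1/α) − lgamma(1/α)` is evaluated as `Σ_{i<y} log(1/α + i)`,
  exact for the small integer outcomes here; the direct `gammaln` difference
  cancels catastrophically as α → 0 and would corrupt the Poisson limit.
* **Continuous families evaluate integer scores as points on the density**
  (no interval-censoring likelihood), matching the common practice of
  treating screening totals as continuous.
* Integer scores include zeros, which log-normal/gamma/Weibull cannot
  evaluate.  When (and only when) a zero is present, *all* values are
  shifted by +0.5 — the smallest half-integer separating 0 from 1 on an
  integer scale — and the shift is recorded on the score vector, carried
  into predicted-distribution grids, and flagged in GOF rows.  A shifted
  −2LL is a statistic of the shifted data; rows are flagged so they are not
  over-interpreted against unshifted rows.

## Estimation

Maximum likelihood by quasi-Newton (BFGS) on an unconstrained scale:
coefficients as-is, positive auxiliaries through log, the GP dispersion
through logit.  Covariate columns are standardised internally for
optimisation and the estimates mapped back to natural units (standard
errors through the full delta-method covariance transform), which keeps the
Hessian well-conditioned with predictors on year scales.  The start is a
method-of-moments estimate; five jittered restarts (configurable) guard
against local optima, and NB/GP additionally start once near the δ, α → 0
boundary because underdispersed data place their MLE there — exactly the
regime where a naive interior start stalls and produces the paradox of a
nesting family apparently fitting worse than the Poisson it nests.  A
damped Newton polish pushes the gradient sup-norm of the mean
log-likelihood below 1e-5 (the convergence tolerance; max 500 BFGS
iterations).  When the moment start already satisfies the likelihood
equations to a tenth of the tolerance (normal and Poisson intercept-only
have closed-form MLEs) it is accepted directly.

Standard errors come from the inverse observed information (numerical
Hessian at the optimum).  If the information is not positive definite the
fit is marked non-converged and standard errors are reported missing — no
pseudo-inverse patching; such failures are informative and rank last in all
comparisons.  `converged` requires both the gradient tolerance and positive
definiteness.

AIC/BIC count *all* free parameters (coefficients plus auxiliary): Poisson
intercept-only k = 1, normal k = 2, two-parameter families with three
covariates k = 5.  Ties in ranking break toward fewer parameters, then
family name.  Non-nested families are compared by information criteria
only — no Vuong-type tests.

## Bootstrap

Unrestricted random resampling: subjects drawn uniformly with replacement
at a 100% rate (every replicate has the original n), B = 10,000 by default.
The percentile interval discards `floor(0.025 B)` order statistics per tail
and takes the min/max of the rest, so endpoints are always observed
replicate values, never interpolated.  Replicate r's RNG stream is spawned
deterministically from (seed, r): results are independent of execution
order.  Non-converged replicates are dropped (retrying would bias the
resampling distribution) and counted; a warning fires above 1% failures.
Per-coefficient p-values use the sign-crossing rule
`2·min(#{draws ≤ 0}, #{draws ≥ 0})/B_successful`, floored at
`1/B_successful` — the construction consistent with percentile intervals.
Replicate GOF means/medians are reported but must not be compared across
bootstrap/non-bootstrap runs; the criteria are model-selection devices
within one setting.

## Synthetic cohort generator

The generator emulates the *structure* such studies exhibit, not any real
cohort: n = 883; age truncated-normal 63.5 ± 7.8 on [40, 90]; 34.2% male;
education gamma moment-matched to 11.6 ± 4.0 years, rounded and clipped to
[0, 23].  Inverse scores come from generalised-Poisson regressions with log
links on centred covariates, signs age +0.02, female −0.05, education −0.06
per unit: a single component with mean 4.4, δ = 0.45 for the unimodal
(MoCA-like) outcome, and a 0.75/0.25 mixture of components with means
3.5/11.0 and δ = 0.20/0.15 for the bimodal (VCAT-like) outcome.  These
values were moment-matched once to the reference margins (score means
24.6/25.6, SDs ≈ 4.5/4.1) and are configurable.  Draws above 30 are
rejected and redrawn — clipping would pile mass at the boundary and create
a spurious ceiling spike.

What the generator does *not* emulate: diagnostic subgroup structure
(SCD vs MCI), item-level response processes, informative missingness, or
the exact empirical shape of any real cohort.  Passing tests therefore
demonstrate that the machinery behaves correctly under a realistic
data-generating mechanism, not that any particular clinical conclusion
transfers.

## Test and verification design

* Family reductions are exact nesting checks: CMP(ν=1) ≡ Poisson and
  GP(δ=0) ≡ Poisson to 1e-10; NB at α = 1e-8 within 1e-5 of Poisson; the
  CMP normaliser against independent brute-force summation.
* Log-densities are verified against extended-precision symbolic evaluation
  (sympy, 40 digits) at grid points, and samplers against their own
  densities by chi-square/KS at α = 0.001 on 1e5 draws.
* Parameter recovery fits each family to its own simulations at the study
  scale (n = 883, 200 replicates; 40 for CMP, whose series normaliser makes
  it the costly family): the 3-SE interval for the intercept must cover
  truth in ≥ 95% of replicates (nominal ≈ 99.7%).
* Bootstrap coverage uses 200 outer replicates at B = 1,000 — scaled down
  from the reference protocol's 10,000 replications — for the normal mean
  under a correctly specified model, asserting 95% ± 2.5%.
* The qualitative selection check generates 50 synthetic cohorts and
  requires GP/NB/gamma to beat normal and Poisson on inverse-orientation
  AIC (and Poisson to be the worst count model) in ≥ 90% of them.

## Known limitations

* GP lacks the underdispersed branch; for underdispersed outcomes CMP
  (ν > 1) is the appropriate candidate.
* CMP coefficients live on the log-rate, not log-mean, scale.
* The +0.5 positivity shift is a convention, not an inference-preserving
  transformation; likelihoods on shifted data are flagged accordingly.
* Integer outcomes are scored by continuous families without interval
  censoring; with only 31 support points this is an approximation accepted
  by design.
* No zero-inflated, hurdle, truncated-at-30 or beta-binomial variants, and
  no random effects or regularisation.
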