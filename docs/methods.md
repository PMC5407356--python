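# Methods

## Model

`mixediou` fits the stochastic linear mixed model of Taylor–Cumberland–Sy
type for longitudinal biomarkers: for subject *i* with responses
*Y<sub>i</sub>* at times *t<sub>i1</sub> ≤ … ≤ t<sub>in_i</sub>*,

    Y_i = X_i β + Z_i b_i + W_i + ε_i,

with mutually independent *b<sub>i</sub>* ~ N(0, G) (unstructured, q×q),
*ε<sub>i</sub>* ~ N(0, σ²I), and *W<sub>i</sub>* an integrated
Ornstein–Uhlenbeck (IOU) process evaluated at the subject's times.  The
IOU process is the time integral of a mean-reverting OU velocity process
with rate α and diffusion scale τ:

    Var W(t)       = (τ²/α³)(αt + e^{−αt} − 1)
    Cov(W(s),W(t)) = (τ²/2α³)(2α·min(s,t) + e^{−αs} + e^{−αt} − 1 − e^{−α|t−s|})

α measures *derivative tracking*: small α means a subject's trajectory
keeps its slope for a long time; as α → ∞ with ω = τ²/α² fixed the process
becomes Brownian motion with Cov → ω·min(s,t); as α → 0 with τ²/2α fixed
it degenerates to an independent random slope.  Both limits are verified
numerically in the test suite, as is agreement of the closed-form kernel
with direct double integration of the OU velocity covariance.

Because the process is nonstationary (Var W(0) = 0) the model needs a
natural time zero; data with negative times are refused unless the user
opts into differencing from a chosen first measurement
(`model_core.difference_from_first`).  The nonstationarity also implies a
rescaling equivalence: the covariance on a grid stretched by Q equals the
original when α → α/Q and ω → ω/Q (τ² → τ²/Q³), implemented as
`rescale_equivalent` and tested as exact matrix equality.

## REML estimation

The marginal covariance is V_i = Z_i G Z_i′ + Γ_i + σ²I.  Writing
V_i = σ²V*_i with V*_i = Z G* Z′ + Γ*(α, a*) + I (G* = G/σ², amplitude
scaled likewise), σ² has the closed-form profile
σ̂² = Σᵢ r_i′V*_i⁻¹r_i/(N−p) with GLS residuals r_i, and the objective
minimized over the reduced vector θ is

    −2ℓ_p(θ) = (N−p)·log σ̂²(θ) + Σᵢ log|V*_i| + log|Σᵢ X_i′V*_i⁻¹X_i| + C,

with the constant C = (N−p)(1 + log 2π) included so that reported REML
deviances — and hence AIC/BIC — share a fixed convention across models.

θ consists of the log-Cholesky encoding of G* (logged diagonal,
unconstrained off-diagonal), one of three coordinates for α (α, log α, or
1/α) and the σ²-scaled amplitude (ω* or τ*) — six IOU parameterizations in
all.  Optimization runs directly on θ; the fully unconstrained scale ρ
(log SDs, atanh correlations, log amplitude, log of the α coordinate,
log σ) is used only for standard errors and interval construction.

### Derivatives

All derivatives are analytic.  ∂V*/∂θ and ∂²V*/∂θ² follow from the
log-Cholesky product rule and from closed-form ∂Γ/∂α, ∂²Γ/∂α² of the IOU
kernel, written in a cancellation-free factored form (see below).  The
score and the observed/expected/average information of the *unprofiled*
objective are assembled in the full coordinates φ = (θ, σ²) from the
standard REML identities (P-matrix trace and quadratic forms), then
profiled to θ by a Schur complement over the σ² row/column — exact for
the gradient and Hessian of the profiled objective because the σ² score
vanishes along the profile.  Finite differences appear only as test
oracles; the suite checks the gradient to 1e−5 and the Hessian against a
second-difference oracle whose error shrinks as h².

Everything is accumulated subject by subject.  Subjects sharing an
identical (times, X, Z) block — all of them, in a balanced design — are
pooled through the sufficient statistics (count, Σy, Σyy′), so one NR
iteration on m = 1000 subjects with n = 20 visits costs the same as on
one subject.  (Sweep/W-transformation shortcuts are an alternative route
to the same quantities and are not used here.)  The per-subject and
dense-stacked computations are tested for equality.

### Optimization and convergence classification

Three schedules: `nr` (observed information), and hybrids `fs_then_nr` /
`ai_then_nr` that run c (default 10) iterations of Fisher scoring or the
average-information algorithm first.  Steps are halved (up to 10 times)
until the objective does not increase, making the deviance trace
monotone; when a curvature matrix is not positive definite a
Marquardt-style ridge is escalated until it factorizes, degrading toward
steepest descent rather than aborting — the standard modified-Newton
behaviour of mixed-model optimizers in flat regions.

A fit is *converged* when the relative deviance change is below 1e−8 and
the scaled gradient below 1e−5 within 100 iterations, **and** the
information matrix for ρ is positive definite (smallest eigenvalue above
1e−6 of the largest; configurable).  Failures are returned, not raised,
with a reason (`max_iter`, `hessian_not_pd`, `info_not_pd`) so simulation
studies can tabulate them.  The EM algorithm is deliberately not offered
as a fitting algorithm (slow, no standard errors); it provides starting
values only.

### Standard errors and intervals

The observed information in φ at the optimum is mapped to ρ with
I_ρ = J⁻ᵀ I_φ J⁻¹, J = ∂ρ/∂φ.  J is obtained by central differences of
the exact, smooth coordinate map (a reparameterization, not a likelihood
derivative; error ~1e−10, far below statistical uncertainty).  95%
intervals are ρ̂ ± 1.959964·se on the ρ scale, with endpoints mapped back
through the (monotone) component transforms, so variance intervals stay
positive and correlation intervals stay inside (−1, 1).  The delta method
to the natural scale is not used (its Jacobian can vanish).

## Numerical choices

* The kernel is evaluated through f(u) = u + e^{−u} − 1 with a 4-term
  Taylor branch below u = 1e−4 (catastrophic cancellation otherwise), and
  the covariance is factored as (ω/2α)[f(u)(1+e^{−d}) − u·expm1(−d)]
  (u = α·min, d = α|s−t|), a sum of nonnegative terms.  The branch is
  tested against a 200-term series at αt down to 1e−14.
* All linear algebra uses Cholesky factorizations; a factorization
  failure raises a domain error (never a silent pseudo-inverse).
* Duplicate visit times are allowed (Γ becomes singular but V stays PD
  through σ²I).
* AIC = −2ℓ_R + 2k and BIC = −2ℓ_R + k·log N with k = fixed + variance
  parameters and N = total observations; comparable only across models
  with identical fixed effects.

## Starting values

* `empirical_start`: across-subject variances of the response at
  regularized times (default grid 3 months, matching the intended visit
  spacing; observed times are rounded to it).  A line fitted to the
  later-time variances gives the intercept → σ_b² start and slope → ω
  start (floored at 1e−4); σ² starts from the gap between the earliest
  variance and the adjacent-time covariance (exactly σ² at t = 0 for a
  random-intercept model).  α has no clean moment estimator: the start is
  ω / (Var̂(t₀) − line(t₀)) — the deviation of the earliest variance from
  the line estimates ω/α — clipped to [0.1, 10].  When the curvature
  signal is absent (weak tracking, small samples) the cap at 10 engages.
* `strong_tracking_start`: a conditional-independence LMM fitted by
  Laird–Ware EM (monotone log-likelihood, tested against statsmodels
  MixedLM) supplies G and σ²; α and ω start at 1 and 0.1.
* `alpha_grid_start`: REML-optimizes the remaining parameters at each
  fixed α on a user grid (masked Newton iterations) and starts from the
  deviance-minimizing grid point; the full (α, deviance) profile is
  returned for flat-likelihood diagnostics.

## Synthetic data: what it emulates and what it does not

The simulators reproduce the designs of HIV-cohort simulation studies on
the fourth-root CD4 scale: balanced m×n designs at k-month spacing from
seroconversion, and a 1489-subject unbalanced cohort (150/224/372/743
subjects with 2/5/10/20 measurements; 20,000 observations) under two
visit-time mechanisms — *target visits* (Normal intervals, mean 91.3
days, SD 31.07 days so 95% of gaps fall between 1 and 5 months, 7-day
floor by redraw) and *intermittent dropout* (sparse subjects draw
lognormal gaps with 95% mass between 6 and 18 months; densely measured
subjects follow the target-visit model).  Visit times are independent of
responses, so missingness is ignorable by construction; the generators do
not emulate informative dropout, assay detection limits, or non-Gaussian
tails, and passing tests therefore say nothing about robustness to those
features.

The tracking truth table (one file: `src/mixediou/tracking.yaml`) pins
β = (4.6, −0.015/month), σ_b² = 0.1156, σ² = 0.04, ω = 0.2/year, and
tracking rates α = 20.7, 5.2, 1.31 per year (weak/moderate/strong; the
internal unit is months).  The rates are quoted on the yearly
time-since-seroconversion scale of the source cohort analyses — checked
here by computing the exact Fisher information: with the per-visit
products αk these values imply (≈5.2 weak, ≈1.3 moderate, ≈0.33 strong at
3-monthly visits), the three regimes reproduce the qualitative behaviour
they are named for: weak tracking has a nearly flat likelihood in α with
bimodal estimates and frequent escapes to the Brownian-motion limit
(classified `info_not_pd`), moderate tracking converges almost always in
4–7 NR iterations with near-nominal coverage, strong tracking converges
essentially always.  ω was fixed at the single value that preserves the
proportionality of the α bias to its true value across visit spacings
while keeping realistic variance growth (~1.0 per 5 years on the CD4^¼
scale); a per-regime ω would match individual failure rates more closely
but is not identifiable from the available information.

## Simulation-study harness

`run_study` derives replicate r of master seed s from the stream (s, r),
so results are independent of execution order and any subset of
replicates is reproducible bit-for-bit.  Summaries follow the standard
evaluation criteria: bias of each variance parameter with Monte Carlo
standard error, empirical SD of the unconstrained transform δ(ν̂), the
median/IQR of its estimated SE, coverage of the nominal 95% interval
(with MCSE 100·√(p(1−p)/n)), iteration medians/IQRs, and failure-reason
counts — computed over converged fits only, with failures always
reported.  Default study sizes in the tests are desk-scale (25–200
replicates); the same harness runs 1000-replicate studies unchanged via
`mixediou simstudy`.

## Known limitations

* ML (unrestricted) estimation, sandwich standard errors,
  profile-likelihood intervals and boundary likelihood-ratio tests are
  out of scope.
* The measurement-error variance is homoscedastic; responses are
  univariate; random effects are nested only (intercept or
  intercept+slope).
* Under weak derivative tracking the α likelihood is genuinely flat near
  the optimum; estimates can escape to the Brownian-motion limit with
  enormous standard errors.  This is a property of the model/design, not
  of the optimizer; the grid-search starts and the `inv_alpha`
  parameterizations mitigate but cannot remove it.
* New-time prediction builds fixed/random designs as intercept+slope
  functions of time; other covariate structures predict at observed times
  only.
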