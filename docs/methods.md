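# Methods

This note records the statistical model, the algorithmic and numerical
choices, and what the synthetic-data checks do and do not establish.

## The doubling identity

Write the model's canonical parameters θ, a scalar target ψ = f(θ), and a
(not necessarily explicit) completion θ ↔ (ψ, λ).  The Laplace approximation
of the posterior of ψ under data y, and under the doubled data (y, y), gives
for their ratio a product of three factors:

1. exp{2 l(ψ, λ̂ψ⁽²⁾; y) − l(ψ, λ̂ψ; y)}, where λ̂ψ and λ̂ψ⁽²⁾ maximize
   l + log π and 2l + log π over λ at fixed ψ;
2. the square-root ratio of the negative λ-Hessians of the doubled- and
   single-data log-posteriors at those maximizers;
3. the ratio of prior densities π(λ̂ψ⁽²⁾|ψ) / π(λ̂ψ|ψ).

If the prior is flat in λ (explicit completion available), both maximizers
solve identical estimating equations, factor 3 is exactly 1, and factor 2 is
the ψ-independent constant 2^{(d−1)/2} (the package computes the determinant
ratio honestly and reports its constancy rather than forcing 1 — only
ψ-dependence matters, since curves are max-normalized).  If instead the
prior is the asymptotic normal N(θ̂, i⁻¹(θ̂)) and the log-likelihood is close
to quadratic, the two negative Hessians are ≈ 3·i_λλ and 2·i_λλ (factor 2 ≈
constant (3/2)^{(d−1)/2}) and factor 3 ≈ 1.  Either way the ratio of
posteriors is the profile likelihood up to a ψ-free constant, and the first
factor is recovered through the classifier described below.  These identities
are verified numerically in the test suite (exactly for factor 3 under flat
priors; to 1e-6 for the 3/2 Hessian scale on an exactly quadratic model).

## Density ratio by classification

Pooling S₂ doubled-data draws (label 1) and S₁ single-data draws (label 0)
of ψ and fitting a logistic regression of the label on a smooth basis in ψ
estimates log{π(ψ|y,y)/π(ψ|y)} + log(S₂/S₁) as the fitted log-odds.  The
intercept (and any additive constant) is irrelevant because curves are
normalized to max 0 on the evaluation grid; the intercept convention anchors
the stored constant at the midpoint of the trusted range.

Smoothers: `quartic` polynomial log-odds (default — simple and hard to
overfit), cubic B-spline (`spline`), the same basis fitted by constrained
maximum likelihood with g″ ≤ 0 at every spline breakpoint
(`concave_spline` — a cubic spline's second derivative is piecewise linear,
so breakpoint constraints give concavity on the whole range), and
`kde_diff`, the difference of two Gaussian kernel log-densities (cross-check
only).  Flexible smoothers are unreliable in the tails, so fits are trusted
only on the intersection of the per-class [q, 1−q] quantile ranges
(q = 0.005 by default); evaluation outside this range raises rather than
extrapolates.  Unequal S₁ ≠ S₂ needs no correction: the count ratio lands in
the discarded intercept.

## Sampler

A many-chain blocked adaptive random-walk Metropolis, fully vectorized
across chains (64 by default — many short chains cover posterior tails
better than one long one, which matters when dividing two estimated
densities):

* the canonical parameters form one block, proposed on the link scale
  (log for positive parameters, logit for probabilities) with a dense
  covariance proposal adapted during warm-up — this follows likelihood
  ridges such as the growth-rate/density-dependence coupling of the
  Beverton–Holt model;
* each cloned latent replicate is split into sub-blocks of ≤ 10 coordinates
  with individually tuned step sizes;
* scalar step sizes per block target 0.28 acceptance; per-coordinate scales
  and the dense factor are re-estimated every 100 warm-up iterations from
  recent history, then frozen (so the post-warm-up chain is a valid
  fixed-kernel Metropolis);
* models that can express their latents as standardized innovations
  (the state-space and random-intercept families) get an *interweaving*
  move: θ is proposed with the innovations held fixed, so scale parameters
  and latent paths move together.  This breaks the funnel coupling between
  a process variance and its path — on the Beverton–Holt example it raises
  the effective sample size of the structural parameters by an order of
  magnitude.

Convergence is summarized by rank-normalized split-Rhat and bulk ESS
(computed via arviz); runs exceeding Rhat 1.1 carry a warning flag but are
not discarded.  A single master seed drives everything through numpy
Generator streams; identical seed + configuration reproduces draws bitwise.
Priors: `flat_box` priors are uniform on the *natural* scale (flatness of
the profiled component on its own scale is what makes the componentwise
algorithm exact); default boxes map a link-scale interval of half-width 20
through the inverse link — proper but effectively flat.

## Data cloning

Replicating the data K times (each copy with its own independent latent
block) concentrates the posterior at the MLE; θ̂ is the posterior mean at
the largest K and K·cov(posterior) estimates i⁻¹(θ̂).  The default schedule
is (1, 2, 4, 8, 16) with warm starts passed up the schedule.  The largest
eigenvalue of the K-scaled covariance is the estimability diagnostic:
stabilization (relative drift < 10% across the last two K) indicates an
identifiable model, roughly linear growth a ridge.  A caveat surfaced by the
state-space example: at small K the posterior mean of a skewed parameter
(e.g. a growth rate) retains O(1/K) skew bias, so cross-checks against the
MLE image use K_max ≥ 8.

## Oracle and quadratic surrogate

For models with an analytic marginal likelihood, the profile is computed by
SLSQP equality-constrained maximization on the link scale, sweeping the grid
outward from the unconstrained MLE with warm starts and up to 5 jittered
restarts per point (profiles of ill-conditioned likelihoods are sensitive to
starting values); infeasible points are dropped with a warning and listed in
curve metadata.  The quadratic surrogate −½(θ−θ̂)ᵀ i (θ−θ̂) is profiled the
same way; for a coordinate ψ it reduces to −(ψ−ψ̂)²/(2 i^{ψψ}).  The
surrogate is deliberately *not* parameterization-invariant — profiling the
beta mean under (mean, α) coordinates gives an exact quadratic whereas the
natural (α, β) coordinates do not — and the suite asserts both facts, since
this contrast is the motivation for the doubling construction.  Hessians are
central finite differences with relative step 1e-4 (the 1e-5 step's
round-off floor of ~5e-6 relative error is too coarse for the 1e-6 checks;
second-difference accuracy is optimized near eps^{1/4}).

## Built-in model families and their generators

* **beta_iid** — i.i.d. beta(α, β); targets: mean, variance, skewness.
  Fixture: α=3, β=2 at n ∈ {10, 50}.  `beta_mean_alpha` re-parameterizes to
  (mean, α) so the mean is a coordinate.
* **mvnormal_iid** — i.i.d. multivariate normal; canonical parameters are d
  means plus the covariance Cholesky factor with log diagonal (box supports,
  positive-definite by construction); target: largest eigenvalue, which is
  invariant to this coordinate choice.
* **sir_binomial** — deterministic discrete-time SIR (Euler, dt = 0.1 day,
  N = 763 by default) with Binomial(N, I_t/N) daily observation; target
  R₀ = β/γ.  The observation model and step size are this package's
  choices for a closed-boarding-school-style outbreak.
* **bevholt_poisson** — latent log-abundance with Beverton–Holt drift and
  process noise σ², Poisson counts; targets: growth rate λ and carrying
  capacity (λ−1)/β.  `bevholt_k` re-parameterizes to (K, β, σ²).  Fixture:
  T = 30, λ = 2, β = 0.01, σ² = 0.01, n₀ = 10 — a series that climbs from
  10 to fluctuate around 100, Paramecium-style.
* **rand_intercept_binom** — paired-arm trials with logit(p_c) = μᵢ,
  logit(p_t) = μᵢ + δᵢ, δᵢ ~ N(δ, 1/τ₁), μᵢ ~ N(μ, 1/τ₂); target: the
  common log-odds ratio δ.  Fixture: 22 trials of 200 per arm, δ = −0.25,
  μ = −2, τ₁ = 25, τ₂ = 4 — chosen for identifiability at this trial count.
* plus diagnostic models: normal mean (known variance), normal
  mean+variance, an exactly-quadratic Gaussian mean model, and a planted
  non-identifiable y ~ N(a+b, 1).

All generators are seeded and bit-reproducible; state-space generators
record the latent path in metadata for tests.  What they deliberately do
not emulate: model misspecification (every fit is well-specified),
overdispersion beyond the stated observation models, missing data, and
continuous-time stochastic epidemic dynamics.  Passing tests therefore
demonstrate correctness of the machinery under the stated models, not
robustness on real data.

## Problem sizes and tolerances in the test suite

Curve-accuracy checks run at stored sample sizes of roughly 20,000 draws
per posterior for analytic models and ~10,000 for the hierarchical ones,
with cross-checks at tolerances of 0.2 log-units against closed forms,
0.5 against the constrained-optimization oracle and between algorithms, and
0.3 for parameterization invariance, evaluated on the central 90% of the
trusted range.  Recovery checks run three seeded replicates per generator
and require all parameters within 3 reported standard errors in ≥ 90% of
replicates.  These sizes are the package's desk-scale defaults; all scale
up through `SamplerConfig`.

## Known limitations

* The doubling identity needs Laplace-regular posteriors; boundary modes,
  multimodality, or non-√n asymptotics break it.
* ψ must be scalar; no simultaneous profiles for vector targets.
* The componentwise route requires an explicit re-parameterization making ψ
  a coordinate; the general route requires an estimable MLE first.
* Random-walk sampling, while robust, is not gradient-based; very
  high-dimensional latent fields (thousands of coordinates) would need a
  different kernel.
* Curve peaks inherit Monte-Carlo error of order (posterior sd)/√ESS; the
  reported grid resolution (101 points over the trusted range) is finer
  than that error, so neighboring grid points are not independent evidence.
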