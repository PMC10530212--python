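# ddprofile

Profile likelihood for hierarchical models by **data doubling**.

## The problem

In hierarchical (latent-variable) models — state-space population dynamics,
random-effects meta-analysis, epidemic curves with noisy observation — the
marginal likelihood involves an integral over the latent variables that is
usually intractable, so classical profile-likelihood inference for a derived
quantity ψ = f(θ) (a reproduction number R₀ = β/γ, a carrying capacity
K = (λ−1)/β, a maximum eigenvalue of a covariance) is out of reach by
constrained optimization.  Bayesian machinery handles the latent integral
effortlessly, but posteriors of derived parameters inherit informative
induced priors and are not parameterization-invariant.

`ddprofile` gets the frequentist object out of the Bayesian machinery.  Let
l_p(ψ; y) = max_λ l(ψ, λ; y) be the log-profile likelihood, with λ the
nuisance coordinates completing θ ↔ (ψ, λ).  Under a prior matched to the
likelihood's curvature, a Laplace expansion shows

  π(ψ | y, y) / π(ψ | y) ∝ exp{ l_p(ψ; y) },

i.e. the ratio of the posterior of ψ under the *doubled* data (y, y) to its
posterior under y is the profile likelihood, up to a constant.  Both
posteriors are routine MCMC targets — doubling the data is the K = 2 case of
data cloning, so any cloning-capable sampler works unmodified.  The ratio is
estimated without density estimation gymnastics: pool the two sets of ψ
draws, label them 1 (doubled) / 0 (single), fit a logistic regression of the
label on a smooth function of ψ — the fitted log-odds, intercept discarded,
is the log density ratio, hence the log-profile likelihood.

Two routes are provided:

* **Algorithm "componentwise, flat prior"** — when ψ is a coordinate of θ,
  flat independent priors suffice and *no MLE is needed*;
* **Algorithm "general function, normal prior"** — for arbitrary scalar
  f(θ), use the asymptotic-normal prior N(θ̂, i⁻¹(θ̂)) obtained by data
  cloning; one (K=1, K=2) sampling pair then profiles *any number* of
  functions at the cost of a logistic fit each.

The package also ships the data-cloning MLE engine with its estimability
diagnostic, an analytic-likelihood oracle (equality-constrained
optimization), the quadratic-surrogate profile (for demonstrating what
non-invariance looks like), Laplace-factor diagnostics, five example model
families with seeded synthetic-data generators, and a CLI.

## Worked example

Profile the mean of a beta(α, β) sample both ways and compare with the
analytic profile:

```python
import numpy as np
from ddprofile import (builtin_psi, fit_mle_dc, lookup_model, oracle_profile,
                       profile_component_flat, profile_function_normalprior,
                       curve_summary, SamplerConfig)
from ddprofile.simulate import gen_beta

data = gen_beta(50, alpha=3.0, beta=2.0, seed=1)
cfg = SamplerConfig(chains=40, draws=500, warmup=800, thin=1, seed=17)

# general-function route: cloned MLE -> normal prior -> doubling pair
model = lookup_model("beta_iid")
mle = fit_mle_dc(model, data, K_schedule=(1, 2, 4, 8))
c2 = profile_function_normalprior(model, data, builtin_psi("beta_mean"),
                                  mle, cfg=cfg)

# componentwise route on the (mean, alpha) parameterization: no MLE needed
c1 = profile_component_flat(lookup_model("beta_mean_alpha"), data, "psi1",
                            cfg=cfg.replace(seed=127))

# analytic oracle by constrained optimization
orc = oracle_profile(model, data, builtin_psi("beta_mean"), c2.psi_grid)

for name, c in [("flat/componentwise", c1), ("normal-prior", c2),
                ("analytic", orc)]:
    psi_hat, (lo, hi), _ = curve_summary(c, level_drop=1.92)
    print(f"{name:20s} psi_hat={psi_hat:.3f}  95% interval=({lo:.3f}, {hi:.3f})")
```

Output from this exact script (seeds as shown):

```
flat/componentwise   psi_hat=0.613  95% interval=(0.560, 0.663)
normal-prior         psi_hat=0.613  95% interval=(0.571, 0.654)
analytic             psi_hat=0.613  95% interval=(0.571, 0.654)
```

All three peak at the MLE image ψ̂ = α̂/(α̂+β̂) ≈ 0.61 (the sample mean) and
give matching asymptotic 95% profile-likelihood intervals — the two
data-doubling curves agree with the constrained-optimization truth without
ever optimizing the likelihood.

The same pipelines run from the shell:

```bash
ddprofile simulate --model beta_iid --n 50 --alpha 3 --beta 2 --seed 1 --out d.csv
ddprofile mle     --model beta_iid --data d.csv --k-schedule 1,2,4,8 --out m.json
ddprofile profile --model beta_iid --data d.csv --psi beta_mean \
                  --algorithm 2 --mle-file m.json --seed 17 --out run1
```

which writes `run1.curve.csv` (101 grid points, max log-profile = 0), a JSON
sidecar with the seed, smoother, trusted range and convergence diagnostics,
and a plain-text run log.

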