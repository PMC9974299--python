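# mcprobit

Mixed cumulative probit (MCP) models: latent-Gaussian prediction of a
single continuous outcome from mixtures of ordinal and continuous
indicators.

## The problem

Estimating a continuous quantity — the motivating case is subadult age
from skeletal and dental indicators — from a panel of indicators that
are partly continuous measurements (e.g. femoral diaphyseal length in
mm) and partly ordinal developmental scores (epiphyseal-fusion stages,
tooth-formation stages). Real indicator panels are nonlinear in the
outcome, heteroscedastic (spread grows with age), conditionally
dependent after accounting for age (a child long for their age in one
bone is long in the others too), and full of missing values, many of
them developmentally structured (an epiphysis cannot be scored before
it appears). Classical transition analysis handles one ordinal
indicator; `mcprobit` generalizes it to the mixed, multivariate,
heteroscedastic, missing-data case.

## The model

For individual with outcome `x > 0`:

- a continuous response is `w ~ N(h(x, c), psi(x, kappa))` with a
  scaled, offset power-law mean `h(x, c) = c2 * x^c1 + c3` and noise
  either constant `psi = kappa1` or linear with positive intercept
  `psi = kappa1 * (1 + kappa2 * x)`;
- an ordinal response arises from a latent `v* ~ N(g(x), gamma(x))` cut
  at ordered thresholds `tau_1 < ... < tau_M`: `v = m` iff
  `tau_m < v* <= tau_{m+1}`. The mean `g` is an unscaled power law
  `x^b1`, `log x`, or `x` (the thresholds absorb location and scale,
  keeping the latent model identifiable); the noise menu is the same as
  for continuous variables. With a linear mean and constant noise this
  is exactly the textbook cumulative (ordered) probit.
- jointly, the latent residuals are multivariate normal with an
  x-independent correlation matrix shared within and between
  user-declared variable *groups* (parameter vector `z`: one term per
  multi-member group plus one per group pair). Missing responses are
  marginalized, which for a multivariate normal is exactly dropping
  them; with all correlations zero the likelihood is exactly the
  product of the univariate likelihoods.

Parameters are estimated by maximum likelihood (quasi-Newton on a
smooth reparametrization, seeded multi-starts). Mean/noise
specifications are chosen per variable by fourfold cross-validated
out-of-sample negative log-likelihood (Step 1), and conditional
dependence vs independence by a second cross-validation on the same
folds (Step 2). Posterior inference over `x` multiplies the fitted
likelihood with a prior (uniform, or an offset Weibull mixture fitted
to reference outcomes) on a grid, reporting the posterior mean and the
2.5%/97.5% equal-tailed interval. Information gain from prior `Q` to
posterior `P` is the Kullback–Leibler divergence in bits,
`sum_n P_n log2(P_n / Q_n)`; the mutual information at a baseline `x0`
is its Monte-Carlo average over response vectors simulated at `x0`.

## Worked example

```python
import numpy as np
import mcprobit as m

# a synthetic six-variable study: 2 long-bone lengths, 4 ordinal scores,
# four dependence groups (8 correlation terms), developmental missingness
data = m.paper_like_fixture(seed=0, n=1296)
specs, theta_true, _, _ = m.paper_like_design()

# Step-1 cross-validation for one variable
folds = m.assign_folds(data.n, K=4, seed=0)
cv = m.crossval_univariate(data, "FDL", folds=folds,
                           options=m.FitOptions(seed=0, n_restarts=2))
print(cv.to_frame().to_string(index=False))
best = cv.best("FDL")
print("preferred:", best.mean_spec, "+", best.noise_spec)

# posterior for one individual under the true model
prior = m.fit_weibull_mixture_prior(data.x, seed=0, max_components=3)
x_calc = m.default_grid(prior, 513)
row = 10
post = m.calc_posterior(data.Y[row], data.mask[row], theta_true,
                        specs, prior, x_calc, mvn_rect_tol=1e-6)
mean, lo, hi = m.point_and_interval(post)
kl = m.kl_divergence(post, m.prior_density(prior, x_calc))
print(f"true age {data.x[row]:.2f}  estimate {mean:.2f} [{lo:.2f}, {hi:.2f}]  "
      f"gain {kl:.2f} bits")
```

Output:

```
variable      mean_spec  noise_spec status         nll
     FDL pow_law_offset       const     ok 4718.131487
     FDL pow_law_offset lin_pos_int     ok 4444.593319
preferred: pow_law_offset + lin_pos_int
true age 11.56  estimate 11.04 [9.71, 12.55]  gain 3.22 bits
```

The cross-validation table mirrors the Step-1 report: the
heteroscedastic noise model wins for a long-bone length by ~270 NLL
units. The posterior concentrates around the true age and quantifies
the information the observed responses carried (about 3 bits relative
to the reference-age prior).

A command-line pipeline (`mcprobit simulate | crossval | fit |
posterior | info`) wraps the same functions around YAML configs and
writes per-run manifests; see `mcprobit --help`.

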