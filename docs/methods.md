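# Methods

## Model

`mcprobit` implements a latent-Gaussian family for predicting one
positive continuous outcome `x` from J mixed responses. Conditioned on
`x`, the vector of latent responses is multivariate normal. Each
variable contributes a mean curve and a noise scale:

- continuous: mean `h(x, c) = c2 x^{c1} + c3`, all `c > 0`, so the
  curve is increasing and starts at the offset `c3` (e.g. a diaphyseal
  length at birth);
- ordinal: mean `g(x) = x^{b1}` (`b1 > 0`), `log x`, or `x`. These are
  deliberately unscaled and unshifted: with free thresholds and a free
  noise scale, a scale or offset on `g` would be redundant, so the
  identifiable parametrization pushes location/scale into the
  thresholds `tau` and noise.
- noise (both types): constant `k1`, or `k1 (1 + k2 x)` with `k1, k2 >
  0` ("linear positive intercept"), which keeps the sd positive at
  `x = 0` and lets spread grow with the outcome.

An ordinal response is the latent value cut at strictly increasing
thresholds, with the half-open convention `v = m` iff
`tau_m < v* <= tau_{m+1}` (`tau_0 = -inf`, `tau_{M+1} = +inf`). The
probit link is a modelling assumption independent of the mean/noise
menu; no other links are offered.

Residual correlations are constant in `x` and shared by group: the
parameter vector `z` has one entry per group with at least two member
variables (within-group term, in order of first appearance) followed by
one entry per unordered group pair (appearance order). Four groups with
two multi-member groups give 2 + 6 = 8 terms. The implied correlation
matrix must be positive definite; this is validated at construction and
enforced with a large finite penalty (not an exception) during
optimization so line searches remain stable.

## Likelihood

One individual's likelihood factorizes as (observed continuous block) x
(observed ordinal block | continuous block). The continuous block is a
multivariate normal density; the ordinal block is the probability that
the conditional latent vector (standard Gaussian conditioning) falls in
the rectangle bounded by the observed stages' thresholds. Conditioning
instead of integrating the full J-dimensional density reduces the
integral dimension to the number of observed ordinal variables; the two
formulations are mathematically identical. Missing components are
marginalized, which for a multivariate normal is row/column deletion —
the implementation literally strips those indices, so "widening a
rectangle to the whole line" and "removing the variable" are the same
computation, and an all-missing row contributes log-likelihood 0.

Rectangle probabilities use a Genz-type sequential transformation
evaluated on scrambled Sobol points: the estimate averages several
independently scrambled point sets (eight for the scalar routine, four
for the row-batched one; all scramblings derived from one seed, so
results are deterministic), doubling the points per set until the
three-sigma spread falls below `mvn_rect_tol` (default 1e-8). Rows that
share a missingness pattern share the conditional correlation matrix,
so their boxes are integrated in one vectorized batch over a common
point set.
Dimensions with `(-inf, inf)` bounds are stripped analytically; a
diagonal (conditional) covariance short-circuits to an exact product of
1-D normal interval probabilities, which is what makes the
conditionally independent model agree with the stacked univariate
likelihoods to floating-point accuracy rather than to QMC tolerance.
One-dimensional intervals use CDF differences with far-tail handling
(survival-function differences beyond 6 sd; exact `log ndtr` for
one-sided intervals). An interval whose probability underflows (below
1e-300) yields `-inf` rather than an exception so optimizers can back
off. Non-finite means or scales (overflow at extreme parameter
proposals, e.g. `x^{b1}` for runaway `b1`) likewise return `-inf`;
without this guard the inf/nan arithmetic can fabricate finite bogus
likelihoods that an optimizer will happily exploit.

Dataset log-likelihoods group rows by missingness pattern (the
correlation blocks are constant per pattern, so the common cases — no
ordinal component, one ordinal component, diagonal conditional
covariance — evaluate vectorized) and combine per-row terms with an
exactly rounded sum (`math.fsum`), making totals independent of row
order.

## Fitting

All constraints are removed by smooth reparametrization: `log` for
positive parameters, `(tau_1, log(tau_2 - tau_1), ...)` for thresholds,
`atanh` for correlations. L-BFGS-B with numerical gradients runs from a
data-driven initialization plus seeded jittered restarts (default 5;
scale 0.5 in the transformed space); the best restart wins and the
initialization itself is always evaluated, so the final NLL can never
exceed it. Initialization: continuous means from a crude linear fit
(slope clipped positive, offset at the minimum response); ordinal
thresholds at probit-transformed empirical cumulative stage
frequencies placed on the location/scale of `g(x)`; `b1 = 1`; noise
slope `k2 = 0.1`. The multivariate fit starts at the stacked univariate
fits with `z = 0` (the conditionally independent model), optionally
freezing the univariate blocks (`fit_z_only`) when only the correlation
structure is of interest.

A fitted heteroscedastic model whose noise slope `k2` exceeds
`max_noise_slope` (default 100 per unit `x`, configurable) is flagged
and the candidate is reported as rejected in cross-validation tables —
such fits describe a noise scale exploding within a single unit of the
outcome, which in practice signals a degenerate optimum rather than
heteroscedasticity.

Known limitation: the ordinal power-law exponent is weakly identified
when the observed `x` range extends far past the last threshold (most
responses sit in the top stage and the likelihood surface has a shallow
ridge trading `b1` against the threshold/noise scale). Recovery
experiments therefore sample `x` across the stage-transition window,
and single-seed parameter errors along that ridge can exceed their
median over replicates.

## Model selection

Step 1 assigns every individual to one of K = 4 evenly sized random
folds (seeded; shared by all variables and both steps, and kept even if
a variable is missing in a row — the per-variable test NLL just skips
masked rows). Each candidate (3 means x 2 noises for ordinal, 1 x 2
for continuous) is fitted per training fold and scored by the summed
held-out negative log-likelihood; the smallest wins, ties breaking
toward fewer parameters then candidate order. AIC on the full-data fit
is available behind a flag but cross-validation is the default. Step 2
compares the stacked (z = 0) model with the conditionally dependent fit
on the same folds. Because the likelihood of the stacked model is
exactly the sum of univariate likelihoods, the conditionally
independent score can be built directly from the Step-1 machinery.

`binned_stage_proportions` provides the visual goodness-of-fit check
for one ordinal stage: equal-count bins in `x`, empirical stage
proportion per bin next to the model probability at the bin mean.

## Prior, posterior, information

The prior over `x` is uniform or an offset Weibull mixture. The mixture
is fitted by EM whose M-step solves each component's weighted Weibull
MLE exactly (1-D bounded search over the shape with the scale profiled
out), so the log-likelihood trace is nondecreasing; three seeded
restarts guard against bad initializations, components with weight
below 1e-6 are pruned, and the component count defaults to BIC over
1..4. The offset defaults to 0 (outcomes measured from birth) and can
be fixed elsewhere by the caller.

Posteriors live on a fixed grid, by default 513 equally spaced points
spanning the prior's 0.0005–0.9995 quantiles. The likelihood is
evaluated in log space at every grid point (reusing the vectorized
dataset path with the case's responses tiled across the grid), shifted
by its maximum, exponentiated, multiplied pointwise by the prior, and
trapezoid-normalized. The point estimate is the trapezoid mean; the
equal-tailed 95% interval interpolates the trapezoid CDF at 0.025 and
0.975 (on an exactly uniform density over (0, 10) this yields exactly
(0.25, 9.75)).

KL divergence is computed in bits on grid *masses* (density times
trapezoid weight, renormalized), not raw densities — the sum form of
the divergence is only meaningful on masses. Terms with zero posterior
mass contribute 0; positive posterior mass where the prior has none
yields +inf with a warning. Mutual information at a baseline `x0` is
plain Monte Carlo (default 500 draws, seeded, no variance-reduction
tricks): simulate response vectors from the fitted model at `x0`,
compute each draw's prior-to-posterior KL, and report mean and standard
error. `ordinalize_continuous` bins a continuous measure with the same
right-closed convention as the thresholds, which makes "FDL as a stage
score" exactly an MCP ordinal model on the identifiable scale
(`tau = (cut - c3)/c2`, noise `k1/c2`), so the continuous-vs-ordinal
information comparison needs no machinery outside the family.

## Synthetic data

The simulator runs the model generatively: outcomes from the declared
prior (optionally truncated by rejection), latent responses
multivariate normal with the grouped correlation structure, ordinal
responses by thresholding, then missingness — MCAR per variable and/or
deterministic observation windows in `x` that emulate developmentally
absent indicators (fusion scores only observable after the epiphysis
appears; ossification counts saturating in childhood). Windows are
deterministic in `x` by design; MCAR layers on top independently.

`paper_like_fixture` is the package's standing six-variable test bed
(n = 1296): two continuous power-law lengths with noise growing roughly
4 to 20 mm across ages 0–22, ordinal variables with M = 3, 5, 11, 11,
four dependence groups giving eight correlation terms, an offset
Weibull mixture age distribution truncated to (0, 22), window
missingness on the fusion/ossification variables and 25%/5% MCAR on the
dental/length variables. The parameter values are arbitrary realistic
constants chosen once for this package; they are not estimates from any
reference sample. The simulator reproduces the model's own
distributional assumptions exactly, so passing recovery and selection
tests demonstrates the correctness of the machinery, not robustness to
real-data features it does not emulate: inter-observer scoring error,
non-Gaussian latent tails, age-dependent correlations (explicitly out
of scope), or informative missingness beyond deterministic windows.

## Problem sizes and numerical defaults

Cross-validation and recovery experiments in the test suite and the
acceptance script use n between 600 and 2000 with 1–3 optimizer
restarts; the acceptance pipeline runs the six-variable study at
n = 1296 with the Step-2 conditional-dependence fit restricted to the
correlation vector (`fit_z_only`, rectangle tolerance 1e-5), which is
the package's scaled-down analogue of a full joint refit — the full
joint fit is exercised in the two-variable tests. Default tolerances:
optimizer `ftol` 1e-8, rectangle probability 1e-8, grid normalization
1e-8. Seeds control every stochastic element (fold assignment, restart
jitter, QMC scrambling, simulation, Monte-Carlo information measures).
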