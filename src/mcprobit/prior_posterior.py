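"""Priors over the outcome, grid-based posterior inference, and information measures.

The Bayesian step treats the fitted response model as the likelihood of a
new individual's response vector as a function of the outcome ``x`` and
combines it with a prior density over ``x`` — either uniform or an offset
Weibull mixture fitted to a reference vector of known outcomes.  Both the
prior and the posterior live on a fixed evaluation grid ``x_calc``: the
prior and likelihood are multiplied pointwise (in log space, for
stability) and the product is trapezoid-normalized to integrate to 1.

Point estimate and uncertainty follow the equal-tailed convention: the
posterior mean, and the 2.5%/97.5% quantiles of the interpolated
trapezoid CDF.  Information gain from prior ``Q`` to posterior ``P`` is
the Kullback–Leibler divergence in bits, ``sum_n P_n log2(P_n / Q_n)``
over grid masses; the mutual information at a baseline outcome ``x0`` is
the Monte-Carlo average of that divergence over response vectors drawn
from the model at ``x0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import weibull_min

from .data_model import DensityGrid, ThetaMultivariate, ValidationError, VariableSpec
from .multivariate import loglik_mixed_rows

__all__ = [
    "PriorSpec",
    "fit_weibull_mixture_prior",
    "prior_density",
    "prior_pdf",
    "sample_prior",
    "default_grid",
    "calc_posterior",
    "point_and_interval",
    "kl_divergence",
    "kl_divergence_masses",
    "mutual_information",
    "ordinalize_continuous",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior over the outcome: uniform on (x_min, x_max) or an offset
    Weibull mixture with components (weight, shape, scale) shifted by x0."""

    kind: str  # "uniform" | "weibull_mixture"
    x_min: float | None = None
    x_max: float | None = None
    x0: float = 0.0
    components: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "uniform":
            if self.x_min is None or self.x_max is None or self.x_min >= self.x_max:
                raise ValidationError("uniform prior needs x_min < x_max")
        elif self.kind == "weibull_mixture":
            if not self.components:
                raise ValidationError("weibull_mixture prior needs components")
            w = np.array([c[0] for c in self.components])
            if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-12:
                raise ValidationError("component weights must be positive and sum to 1")
            if any(c[1] <= 0 or c[2] <= 0 for c in self.components):
                raise ValidationError("shapes and scales must be positive")
            if self.x0 < 0:
                raise ValidationError("offset x0 must be >= 0")
        else:
            raise ValidationError(f"unknown prior kind {self.kind!r}")


def prior_pdf(prior: PriorSpec, x) -> np.ndarray:
    """Raw prior density evaluated at ``x`` (no grid normalization)."""
    x = np.asarray(x, dtype=float)
    if prior.kind == "uniform":
        inside = (x >= prior.x_min) & (x <= prior.x_max)
        return np.where(inside, 1.0 / (prior.x_max - prior.x_min), 0.0)
    t = x - prior.x0
    f = np.zeros_like(t)
    pos = t > 0
    for w, shape, scale in prior.components:
        f[pos] += w * weibull_min.pdf(t[pos], shape, scale=scale)
    return f


def sample_prior(prior: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if prior.kind == "uniform":
        return rng.uniform(prior.x_min, prior.x_max, size=n)
    w = np.array([c[0] for c in prior.components])
    comp = rng.choice(len(w), size=n, p=w / w.sum())
    out = np.empty(n)
    for k, (_, shape, scale) in enumerate(prior.components):
        m = comp == k
        out[m] = weibull_min.rvs(shape, scale=scale, size=int(m.sum()), random_state=rng)
    return out + prior.x0


def _prior_quantile(prior: PriorSpec, q: float) -> float:
    if prior.kind == "uniform":
        return prior.x_min + q * (prior.x_max - prior.x_min)
    # numeric inversion of the mixture CDF
    hi = prior.x0 + max(
        weibull_min.ppf(0.99999, shape, scale=scale) for _, shape, scale in prior.components
    )
    xs = np.linspace(prior.x0, hi, 4097)
    cdf = np.zeros_like(xs)
    t = xs - prior.x0
    for w, shape, scale in prior.components:
        cdf += w * weibull_min.cdf(t, shape, scale=scale)
    return float(np.interp(q, cdf, xs))


def default_grid(prior: PriorSpec, n: int = 513) -> np.ndarray:
    """Evaluation grid spanning the prior's 0.0005–0.9995 quantiles."""
    lo = _prior_quantile(prior, 0.0005)
    hi = _prior_quantile(prior, 0.9995)
    return np.linspace(lo, hi, n)


def prior_density(prior: PriorSpec, x_calc) -> DensityGrid:
    """Prior evaluated and trapezoid-normalized on the grid."""
    x_calc = np.asarray(x_calc, dtype=float)
    f = prior_pdf(prior, x_calc)
    if np.trapezoid(f, x_calc) <= 0:
        raise ValidationError("grid lies entirely outside the prior's support")
    return DensityGrid(x_calc, f).normalize()


# ---------------------------------------------------------------------------
# offset Weibull mixture fitting (EM)


def _weibull_wnll(t: np.ndarray, r: np.ndarray, shape: float) -> tuple[float, float]:
    """Weighted Weibull NLL profiled over scale; returns (nll, scale_hat)."""
    rw = r.sum()
    scale = (np.sum(r * t**shape) / rw) ** (1.0 / shape)
    logpdf = (
        np.log(shape) - shape * np.log(scale) + (shape - 1.0) * np.log(t) - (t / scale) ** shape
    )
    return -float(np.sum(r * logpdf)), float(scale)


def _em_weibull_mixture(
    t: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_starts: int = 3,
) -> tuple[list[tuple[float, float, float]], list[float]]:
    """EM for a k-component Weibull mixture on positive data ``t``.

    M-step solves each component's weighted MLE exactly (1-D search over
    the shape with the scale profiled out), so the log-likelihood trace is
    nondecreasing within a start; the best of ``n_starts`` seeded
    initializations wins.
    """
    best: tuple[list, list] | None = None
    for start in range(n_starts if k > 1 else 1):
        comps, trace = _em_weibull_once(t, k, rng if start else None, max_iter, tol)
        if best is None or trace[-1] > best[1][-1]:
            best = (comps, trace)
    return best


def _em_weibull_once(
    t: np.ndarray, k: int, rng, max_iter: int, tol: float
) -> tuple[list[tuple[float, float, float]], list[float]]:
    n = t.size
    qs = np.quantile(t, np.linspace(0, 1, k + 1))
    comps = []
    for j in range(k):
        sel = (t >= qs[j]) & (t <= qs[j + 1])
        seg = t[sel] if sel.sum() >= 5 else t
        m, s = seg.mean(), max(seg.std(), 1e-6 * t.mean())
        shape = float(np.clip((s / m) ** -1.086, 0.2, 20.0))  # moment start
        if rng is not None:  # jittered restart
            shape = float(np.clip(shape * np.exp(0.3 * rng.standard_normal()), 0.1, 40.0))
            m = float(m * np.exp(0.3 * rng.standard_normal()))
        comps.append([1.0 / k, shape, m])
    trace: list[float] = []
    for _ in range(max_iter):
        dens = np.column_stack(
            [w * weibull_min.pdf(t, a, scale=s) for w, a, s in comps]
        )
        tot = dens.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.sum(np.log(tot)))
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol * (1 + abs(trace[-2])):
            break
        resp = dens / tot[:, None]
        for j in range(k):
            r = resp[:, j]
            rw = r.sum()
            if rw < 1e-9:
                continue
            res = minimize_scalar(
                lambda la: _weibull_wnll(t, r, np.exp(la))[0],
                bounds=(np.log(0.05), np.log(50.0)),
                method="bounded",
            )
            shape = float(np.exp(res.x))
            _, scale = _weibull_wnll(t, r, shape)
            comps[j] = [rw / n, shape, scale]
    return [tuple(c) for c in comps], trace


def fit_weibull_mixture_prior(
    x_known,
    n_components: int | None = None,
    x0: float = 0.0,
    seed: int = 0,
    max_components: int = 4,
    full_output: bool = False,
):
    """Maximum-likelihood offset Weibull mixture prior for the outcome.

    With ``n_components=None`` the count is chosen by BIC over
    ``1..max_components``.  Components whose weight collapses below 1e-6
    are pruned with a warning.  Returns a :class:`PriorSpec` (and the EM
    log-likelihood trace of the winning fit when ``full_output``).
    """
    x_known = np.asarray(x_known, dtype=float)
    if np.any(x_known <= x0):
        raise ValidationError("x_known must exceed the offset x0")
    t = x_known - x0
    rng = np.random.default_rng(seed)
    candidates = [n_components] if n_components else list(range(1, max_components + 1))
    best = None
    for k in candidates:
        comps, trace = _em_weibull_mixture(t, k, rng)
        ll = trace[-1]
        n_par = 3 * k - 1
        bic = n_par * np.log(t.size) - 2.0 * ll
        if best is None or bic < best[0]:
            best = (bic, comps, trace)
    _, comps, trace = best
    kept = [c for c in comps if c[0] >= 1e-6]
    if len(kept) < len(comps):
        warnings.warn(f"pruned {len(comps) - len(kept)} degenerate mixture component(s)")
    w = np.array([c[0] for c in kept])
    comps = tuple((wi / w.sum(), a, s) for wi, (_, a, s) in zip(w, kept))
    prior = PriorSpec(kind="weibull_mixture", x0=x0, components=comps)
    if full_output:
        return prior, trace
    return prior


# ---------------------------------------------------------------------------
# posterior inference


def calc_posterior(
    y,
    mask,
    theta: ThetaMultivariate,
    specs: Sequence[VariableSpec],
    prior: PriorSpec,
    x_calc,
    mvn_rect_tol: float = 1e-8,
    seed: int = 0,
) -> DensityGrid:
    """Grid posterior over the outcome for one individual's responses.

    The likelihood is evaluated in log space at every grid point, the
    maximum is subtracted before exponentiating, and the pointwise product
    with the prior is normalized to integrate to 1.  With every response
    missing the posterior equals the prior.
    """
    from .data_model import MixedDataset

    x_calc = np.asarray(x_calc, dtype=float)
    q = prior_density(prior, x_calc)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return q
    n = x_calc.size
    grid_data = MixedDataset(
        x=x_calc,
        Y=np.tile(np.asarray(y, dtype=float), (n, 1)),
        mask=np.tile(mask, (n, 1)),
        specs=tuple(specs),
    )
    ll = loglik_mixed_rows(grid_data, theta, mvn_rect_tol=mvn_rect_tol, seed=seed)
    finite = np.isfinite(ll) & (q.f > 0)
    if not finite.any():
        raise ValidationError("likelihood underflowed at every grid point")
    f = np.zeros(n)
    shift = ll[finite].max()
    f[finite] = np.exp(ll[finite] - shift) * q.f[finite]
    return DensityGrid(x_calc, f).normalize()


def point_and_interval(posterior: DensityGrid, level: float = 0.95) -> tuple[float, float, float]:
    """(posterior mean, lower, upper) with an equal-tailed interval.

    The mean integrates ``x f(x)`` by the trapezoid rule; the quantiles
    linearly interpolate the trapezoid CDF at (1-level)/2 and 1-(1-level)/2.
    """
    x, f = posterior.x_calc, posterior.f
    mean = float(np.trapezoid(x * f, x))
    dx = np.diff(x)
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * dx)))
    cdf /= cdf[-1]
    alpha = (1.0 - level) / 2.0
    lower = float(np.interp(alpha, cdf, x))
    upper = float(np.interp(1.0 - alpha, cdf, x))
    return mean, lower, upper


# ---------------------------------------------------------------------------
# information measures


def kl_divergence_masses(p, q) -> float:
    """KL divergence in bits between two discrete mass vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    out = 0.0
    for pi, qi in zip(p, q):
        if pi == 0.0:
            continue
        if qi == 0.0:
            warnings.warn("posterior mass where the prior has none: KL is infinite")
            return float("inf")
        out += pi * np.log2(pi / qi)
    return max(out, 0.0)


def kl_divergence(P: DensityGrid, Q: DensityGrid) -> float:
    """KL divergence of posterior ``P`` from prior ``Q`` in bits.

    Densities on the shared grid are converted to masses with trapezoid
    weights and renormalized; terms with ``P_n = 0`` contribute 0.
    """
    if P.x_calc.shape != Q.x_calc.shape or not np.allclose(P.x_calc, Q.x_calc):
        raise ValidationError("P and Q must share the same evaluation grid")
    x = P.x_calc
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += 0.5 * dx
    w[1:] += 0.5 * dx
    return kl_divergence_masses(P.f * w, Q.f * w)


def mutual_information(
    x0: float,
    theta: ThetaMultivariate,
    specs: Sequence[VariableSpec],
    prior: PriorSpec,
    x_calc,
    n_draws: int = 500,
    seed: int = 0,
    mvn_rect_tol: float = 1e-8,
) -> tuple[float, float]:
    """Monte-Carlo mutual information (bits) at baseline outcome ``x0``.

    Draws ``n_draws`` response vectors from the fitted model at ``x0``,
    computes the prior-to-posterior KL divergence for each, and returns
    the average with its Monte-Carlo standard error.  This is the expected
    information a response vector carries about the outcome at that
    baseline.
    """
    from .synthetic_data import simulate_responses

    rng = np.random.default_rng(seed)
    x_calc = np.asarray(x_calc, dtype=float)
    q = prior_density(prior, x_calc)
    Y, _ = simulate_responses(np.full(n_draws, float(x0)), theta, specs, rng)
    kls = np.empty(n_draws)
    full_mask = np.ones(len(specs), dtype=bool)
    for i in range(n_draws):
        post = calc_posterior(
            Y[i], full_mask, theta, specs, prior, x_calc,
            mvn_rect_tol=mvn_rect_tol, seed=seed,
        )
        kls[i] = kl_divergence(post, q)
    mi = float(np.mean(kls))
    se = float(np.std(kls, ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else float("nan")
    return mi, se


def ordinalize_continuous(w, cutpoints) -> np.ndarray:
    """Bin a continuous value into stages: ``m`` iff ``cut_m < w <= cut_{m+1}``.

    Right-closed, matching the threshold convention of the latent ordinal
    model; a value equal to a cutpoint takes the lower stage.
    """
    cutpoints = np.asarray(cutpoints, dtype=float)
    if cutpoints.ndim != 1 or (cutpoints.size > 1 and np.any(np.diff(cutpoints) <= 0)):
        raise ValidationError("cutpoints must be strictly increasing")
    w = np.asarray(w, dtype=float)
    return np.searchsorted(cutpoints, w, side="left")
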