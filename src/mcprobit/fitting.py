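"""Constrained maximum-likelihood fitting via smooth reparametrization.

All constrained parameters are mapped to an unconstrained space before
optimization: positive parameters through ``log``, the ordered thresholds
through ``(tau_1, log(tau_2 - tau_1), ...)``, and correlations in (-1, 1)
through ``atanh``.  A quasi-Newton search (L-BFGS-B with numerical
gradients) is run from the data-driven initialization plus seeded jittered
restarts, and the best restart wins.  The final negative log-likelihood is
never worse than the initialization because the initialization itself is
one of the evaluated points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtri

from .data_model import (
    MixedDataset,
    ThetaMultivariate,
    ThetaUnivariate,
    ValidationError,
    VariableSpec,
)
from .multivariate import loglik_mixed_dataset
from .response_models import loglik_univariate, mean_ordinal

__all__ = [
    "FitOptions",
    "FitReport",
    "FitError",
    "transform_univariate",
    "untransform_univariate",
    "transform_multivariate",
    "untransform_multivariate",
    "fit_univariate",
    "fit_multivariate",
]

_PENALTY = 1e10


class FitError(RuntimeError):
    """Raised when no restart produces a usable fit."""


@dataclass(frozen=True)
class FitOptions:
    n_restarts: int = 5
    seed: int = 0
    tolerance: float = 1e-8
    max_iter: int = 500
    mvn_rect_tol: float = 1e-8
    max_noise_slope: float = 100.0  # per unit x; larger fitted k2 flags the fit
    jitter_scale: float = 0.5
    method: str = "L-BFGS-B"  # or any scipy.optimize method, e.g. Nelder-Mead

    def __post_init__(self) -> None:
        if self.n_restarts < 1 or self.tolerance <= 0 or self.max_iter < 1:
            raise ValidationError("FitOptions fields must be positive")


@dataclass
class FitReport:
    theta_hat: ThetaUnivariate | ThetaMultivariate
    nll_final: float
    converged: bool
    n_restarts_used: int
    best_restart_seed: int
    large_noise_slope: bool = False


# ---------------------------------------------------------------------------
# reparametrization


def transform_univariate(theta: ThetaUnivariate, spec: VariableSpec) -> np.ndarray:
    """Map a univariate parameter block to an unconstrained vector."""
    parts: list[float] = [np.log(v) for v in theta.mean]
    if spec.is_ordinal:
        tau = np.asarray(theta.tau, dtype=float)
        if tau.size != spec.M:
            raise ValidationError(f"expected {spec.M} thresholds, got {tau.size}")
        d = np.diff(tau)
        if tau.size > 1 and np.any(d <= 0):
            raise ValidationError("thresholds must be strictly increasing")
        parts += [tau[0], *np.log(d)]
    parts += [np.log(v) for v in theta.noise]
    return np.array(parts, dtype=float)


def untransform_univariate(vec: np.ndarray, spec: VariableSpec) -> ThetaUnivariate:
    vec = np.asarray(vec, dtype=float)
    n_mean = _n_mean_params(spec)
    n_noise = 1 if spec.noise_spec == "const" else 2
    pos = 0
    mean = tuple(np.exp(vec[pos : pos + n_mean]))
    pos += n_mean
    tau: tuple[float, ...] = ()
    if spec.is_ordinal:
        t0 = vec[pos]
        deltas = np.exp(vec[pos + 1 : pos + spec.M])
        tau = tuple(np.concatenate(([t0], t0 + np.cumsum(deltas))))
        pos += spec.M
    noise = tuple(np.exp(vec[pos : pos + n_noise]))
    return ThetaUnivariate(mean=mean, noise=noise, tau=tau)


def _n_mean_params(spec: VariableSpec) -> int:
    if not spec.is_ordinal:
        return 3
    return 1 if spec.mean_spec == "pow_law" else 0


def _n_univariate_params(spec: VariableSpec) -> int:
    n = _n_mean_params(spec) + (1 if spec.noise_spec == "const" else 2)
    if spec.is_ordinal:
        n += spec.M
    return n


def transform_multivariate(theta: ThetaMultivariate, specs: Sequence[VariableSpec]) -> np.ndarray:
    z = np.asarray(theta.z, dtype=float)
    if np.any(np.abs(z) >= 1):
        raise ValidationError("z must lie strictly inside (-1, 1)")
    blocks = [transform_univariate(t, s) for t, s in zip(theta.thetas, specs)]
    return np.concatenate(blocks + [np.arctanh(z)])


def untransform_multivariate(
    vec: np.ndarray, specs: Sequence[VariableSpec], grouping: Sequence[str], n_z: int
) -> ThetaMultivariate:
    vec = np.asarray(vec, dtype=float)
    thetas = []
    pos = 0
    for spec in specs:
        k = _n_univariate_params(spec)
        thetas.append(untransform_univariate(vec[pos : pos + k], spec))
        pos += k
    z = np.tanh(vec[pos : pos + n_z])
    return ThetaMultivariate(thetas=tuple(thetas), z=tuple(z), grouping=tuple(grouping))


# ---------------------------------------------------------------------------
# initialization


def _init_continuous(x: np.ndarray, y: np.ndarray, spec: VariableSpec) -> ThetaUnivariate:
    slope = np.cov(x, y)[0, 1] / max(np.var(x), 1e-12)
    c2 = max(slope, 1e-3)
    c3 = max(y.min() - c2 * x.min(), 1e-3)
    resid = y - (c2 * x + c3)
    k1 = max(np.std(resid), 1e-3)
    noise = (k1,) if spec.noise_spec == "const" else (k1, 0.1)
    return ThetaUnivariate(mean=(1.0, c2, c3), noise=noise)


def _init_ordinal(x: np.ndarray, v: np.ndarray, spec: VariableSpec) -> ThetaUnivariate:
    b = (1.0,) if spec.mean_spec == "pow_law" else ()
    g = mean_ordinal(x, spec.mean_spec, b)
    loc, scale = float(np.mean(g)), max(float(np.std(g)), 1e-3)
    # probit-transformed empirical cumulative stage frequencies, placed on
    # the latent scale of g(x)
    cum = np.array([np.mean(v < m) for m in range(1, spec.M + 1)])
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    cum = np.maximum.accumulate(cum + 1e-6 * np.arange(spec.M))
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    tau = loc + scale * ndtri(cum)
    tau = np.maximum.accumulate(tau + 1e-6 * np.arange(spec.M))
    for m in range(1, spec.M):
        if tau[m] <= tau[m - 1]:
            tau[m] = tau[m - 1] + 1e-3
    noise = (scale,) if spec.noise_spec == "const" else (scale, 0.1)
    return ThetaUnivariate(mean=b, noise=noise, tau=tuple(tau))


# ---------------------------------------------------------------------------
# optimization driver


def _multistart_minimize(objective, v0: np.ndarray, options: FitOptions):
    """Seeded multi-start quasi-Newton minimization; returns (v, nll, ok, seed)."""
    rng = np.random.default_rng(options.seed)
    best_v, best_nll, best_seed = v0, objective(v0), -1
    any_success = False
    for k in range(options.n_restarts):
        restart_seed = int(rng.integers(2**31)) if k else options.seed
        start = v0 if k == 0 else v0 + options.jitter_scale * np.random.default_rng(
            restart_seed
        ).standard_normal(v0.size)
        if options.method == "L-BFGS-B":
            opt = {"maxiter": options.max_iter, "ftol": options.tolerance, "gtol": 1e-8}
        elif options.method == "Nelder-Mead":
            opt = {"maxiter": 200 * options.max_iter, "fatol": options.tolerance,
                   "xatol": 1e-6}
        else:
            opt = {"maxiter": options.max_iter}
        res = minimize(objective, start, method=options.method, options=opt)
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_v, best_nll, best_seed = res.x, float(res.fun), restart_seed
        any_success = any_success or (res.success and np.isfinite(res.fun))
    return best_v, best_nll, any_success, best_seed


def fit_univariate(
    data: MixedDataset,
    variable: str,
    mean_spec: str | None = None,
    noise_spec: str | None = None,
    options: FitOptions = FitOptions(),
) -> FitReport:
    """Maximum-likelihood fit of one variable's mean/noise(/threshold) block.

    ``mean_spec``/``noise_spec`` override the candidate recorded on the
    variable's spec, which is how cross-validation sweeps the model menu.
    """
    j = data.column(variable)
    spec = data.specs[j]
    if mean_spec or noise_spec:
        spec = spec.with_candidates(mean_spec or spec.mean_spec, noise_spec or spec.noise_spec)
    x, y = data.observed(variable)
    min_obs = max(10, 2 * (spec.M or 0) + 4)
    if y.size == 0:
        raise FitError(f"{variable}: all values missing")
    if y.size < min_obs:
        raise FitError(f"{variable}: needs >= {min_obs} observed values, got {y.size}")
    if np.unique(x).size < 2:
        raise FitError(f"{variable}: x has a single unique value; mean not identifiable")
    if spec.is_ordinal and np.unique(y).size < 2:
        raise FitError(f"{variable}: needs >= 2 distinct observed stages")

    theta0 = _init_ordinal(x, y, spec) if spec.is_ordinal else _init_continuous(x, y, spec)
    v0 = transform_univariate(theta0, spec)

    def objective(vec: np.ndarray) -> float:
        try:
            th = untransform_univariate(vec, spec)
            ll = loglik_univariate(y, x, th, spec)
        except (ValidationError, FloatingPointError, OverflowError):
            return _PENALTY
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    best_v, best_nll, ok, best_seed = _multistart_minimize(objective, v0, options)
    if best_nll >= _PENALTY:
        raise FitError(f"{variable}: optimizer failed on all {options.n_restarts} restarts")
    theta_hat = untransform_univariate(best_v, spec)
    slope_flag = (
        spec.noise_spec == "lin_pos_int" and theta_hat.noise[1] > options.max_noise_slope
    )
    return FitReport(
        theta_hat=theta_hat,
        nll_final=best_nll,
        converged=ok,
        n_restarts_used=options.n_restarts,
        best_restart_seed=best_seed,
        large_noise_slope=slope_flag,
    )


def fit_multivariate(
    data: MixedDataset,
    univariate_fits: Sequence[ThetaUnivariate],
    grouping: Sequence[str] | None = None,
    options: FitOptions = FitOptions(),
    fit_z_only: bool = False,
) -> FitReport:
    """Joint fit of all parameter blocks plus the grouped correlations.

    Initialized at the stacked univariate fits with ``z = 0`` (the
    conditionally independent model), so the final likelihood can only
    improve on conditional independence.  Proposals with a non-positive-
    definite implied correlation matrix incur a large finite penalty
    rather than an exception, keeping line searches stable.  With
    ``fit_z_only`` the univariate blocks are frozen and only ``z`` moves.
    """
    specs = data.specs
    grouping = tuple(grouping if grouping is not None else (s.group for s in specs))
    from .data_model import n_correlation_terms

    n_z = n_correlation_terms(grouping)
    theta0 = ThetaMultivariate(
        thetas=tuple(univariate_fits), z=(0.0,) * n_z, grouping=grouping
    )
    v_full0 = transform_multivariate(theta0, specs)
    n_block = v_full0.size - n_z

    if fit_z_only:
        frozen = v_full0[:n_block]

        def expand(vec):
            return np.concatenate([frozen, vec])

        v0 = v_full0[n_block:]
    else:

        def expand(vec):
            return vec

        v0 = v_full0

    def objective(vec: np.ndarray) -> float:
        try:
            th = untransform_multivariate(expand(vec), specs, grouping, n_z)
            ll = loglik_mixed_dataset(
                data, th, mvn_rect_tol=options.mvn_rect_tol, seed=options.seed
            )
        except (ValidationError, np.linalg.LinAlgError):
            return _PENALTY
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    best_v, best_nll, ok, best_seed = _multistart_minimize(objective, v0, options)
    if best_nll >= _PENALTY:
        raise FitError(f"multivariate fit failed on all {options.n_restarts} restarts")
    theta_hat = untransform_multivariate(expand(best_v), specs, grouping, n_z)
    return FitReport(
        theta_hat=theta_hat,
        nll_final=best_nll,
        converged=ok,
        n_restarts_used=options.n_restarts,
        best_restart_seed=best_seed,
    )
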