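"""Mean and noise response functions, stage probabilities, univariate likelihoods.

A continuous response ``w`` is modelled as ``w ~ N(h(x, c), psi(x, k))``
with a scaled, offset power-law mean ``h(x, c) = c2*x^c1 + c3`` and either
constant (``psi = k1``) or linear-positive-intercept
(``psi = k1*(1 + k2*x)``) noise.  An ordinal response ``v`` arises from a
latent ``v* ~ N(g(x), gamma(x))`` cut at ordered thresholds ``tau``:
``v = m`` iff ``tau_m < v* <= tau_{m+1}`` with ``tau_0 = -inf`` and
``tau_{M+1} = +inf``.  The ordinal mean is unscaled and unshifted
(``x^b1``, ``log x`` or ``x``) so that the thresholds absorb location and
scale, keeping the latent model identifiable.  The normal latent noise
makes this a probit model; with a linear mean and constant noise the
single-variable likelihood is exactly the textbook cumulative (ordered)
probit.

Notation note: the noise parameters of ordinal variables are called beta
in parts of the transition-analysis literature; here both variable types
use the same ``(k1[, k2])`` structure under the name ``noise``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr

from .data_model import ThetaUnivariate, ValidationError, VariableSpec

__all__ = [
    "mean_continuous",
    "mean_ordinal",
    "mean_response",
    "noise_sd",
    "stage_probabilities",
    "loglik_continuous_univariate",
    "loglik_ordinal_univariate",
    "loglik_univariate",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def mean_continuous(x, c) -> np.ndarray:
    """Scaled, offset power-law mean ``c2 * x**c1 + c3``; strictly increasing."""
    c1, c2, c3 = c
    if c1 <= 0 or c2 <= 0 or c3 <= 0:
        raise ValidationError(f"continuous mean parameters must be positive, got {c}")
    x = np.asarray(x, dtype=float)
    return c2 * np.power(x, c1) + c3


def mean_ordinal(x, mean_spec: str, b=()) -> np.ndarray:
    """Unscaled, unshifted ordinal latent mean: ``x**b1``, ``log x`` or ``x``."""
    x = np.asarray(x, dtype=float)
    b = tuple(np.atleast_1d(b)) if b is not None and len(np.atleast_1d(b)) else ()
    if mean_spec == "pow_law":
        if len(b) != 1 or b[0] <= 0:
            raise ValidationError(f"pow_law mean needs a single positive b1, got {b}")
        return np.power(x, b[0])
    if b:
        raise ValidationError(f"mean_spec {mean_spec!r} takes no parameters, got {b}")
    if mean_spec == "log":
        return np.log(x)
    if mean_spec == "lin":
        return x + 0.0
    raise ValidationError(f"unknown ordinal mean_spec {mean_spec!r}")


def mean_response(x, theta: ThetaUnivariate, spec: VariableSpec) -> np.ndarray:
    if spec.is_ordinal:
        return mean_ordinal(x, spec.mean_spec, theta.mean)
    return mean_continuous(x, theta.mean)


def noise_sd(x, noise_spec: str, k) -> np.ndarray:
    """Noise sd: ``k1`` (const) or ``k1*(1 + k2*x)`` (linear positive intercept)."""
    k = tuple(np.atleast_1d(k))
    x = np.asarray(x, dtype=float)
    if any(v <= 0 for v in k):
        raise ValidationError(f"noise parameters must be positive, got {k}")
    if noise_spec == "const":
        if len(k) != 1:
            raise ValidationError(f"const noise takes one parameter, got {k}")
        return np.broadcast_to(np.float64(k[0]), x.shape).copy() if x.ndim else np.float64(k[0])
    if noise_spec == "lin_pos_int":
        if len(k) != 2:
            raise ValidationError(f"lin_pos_int noise takes two parameters, got {k}")
        return k[0] * (1.0 + k[1] * x)
    raise ValidationError(f"unknown noise_spec {noise_spec!r}")


def _padded_tau(tau, M: int) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (M,):
        raise ValidationError(f"need {M} thresholds, got {tau.shape}")
    if M > 1 and not np.all(np.diff(tau) > 0):
        raise ValidationError(f"thresholds must be strictly increasing, got {tau}")
    return np.concatenate(([-np.inf], tau, [np.inf]))


def _interval_prob(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """P(lo < Z <= hi) for standard normal, stable in both tails.

    Computed as ndtr(hi) - ndtr(lo) except when both standardized bounds
    sit in the same far tail, where the difference of upper-tail survival
    probabilities avoids catastrophic cancellation.
    """
    p = ndtr(hi) - ndtr(lo)
    far_right = lo > 6.0
    if np.any(far_right):
        p = np.where(far_right, ndtr(-lo) - ndtr(-hi), p)
    return np.clip(p, 0.0, 1.0)


def stage_probabilities(x, theta: ThetaUnivariate, spec: VariableSpec) -> np.ndarray:
    """P(v = m | x) for m = 0..M; rows sum to 1.

    For scalar ``x`` returns shape ``(M+1,)``; for a vector of n values,
    shape ``(n, M+1)``.
    """
    if not spec.is_ordinal:
        raise ValidationError("stage probabilities are defined for ordinal variables")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    g = mean_ordinal(xv, spec.mean_spec, theta.mean)
    gamma = noise_sd(xv, spec.noise_spec, theta.noise)
    t = _padded_tau(theta.tau, spec.M)  # (M+2,)
    zs = (t[None, :] - g[:, None]) / gamma[:, None]
    p = _interval_prob(zs[:, :-1], zs[:, 1:])
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if scalar else p


def loglik_continuous_univariate(w, x, theta: ThetaUnivariate, spec: VariableSpec) -> float:
    """Sum over observations of the normal log-density of ``w`` given ``x``.

    An empty observation vector contributes 0 (log of an empty product),
    which anchors the missing-data marginalization contract.
    """
    w = np.atleast_1d(np.asarray(w, dtype=float))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if w.size == 0:
        return 0.0
    with np.errstate(over="ignore", invalid="ignore"):
        mu = mean_continuous(x, theta.mean)
        sd = noise_sd(x, spec.noise_spec, theta.noise)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sd))):
        return -np.inf  # overflowed mean/scale: reject the parameter point
    z = (w - mu) / sd
    return float(np.sum(-0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI))


def loglik_ordinal_univariate(v, x, theta: ThetaUnivariate, spec: VariableSpec) -> float:
    """Cumulative-probit log-likelihood summed over observations.

    Returns ``-inf`` (not an exception) when any observed stage has zero
    probability under ``theta``, so that optimizers can reject the point.
    """
    v = np.atleast_1d(np.asarray(v))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if v.size == 0:
        return 0.0
    vi = v.astype(int)
    if np.any(vi != v) or vi.min() < 0 or vi.max() > spec.M:
        raise ValidationError(f"ordinal values must lie in 0..{spec.M}")
    with np.errstate(over="ignore", invalid="ignore"):
        g = mean_ordinal(x, spec.mean_spec, theta.mean)
        gamma = noise_sd(x, spec.noise_spec, theta.noise)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(gamma))):
        return -np.inf  # overflowed mean/scale: reject the parameter point
    t = _padded_tau(theta.tau, spec.M)
    lo = (t[vi] - g) / gamma
    hi = (t[vi + 1] - g) / gamma
    p = _interval_prob(lo, hi)
    # log(Phi(hi) - Phi(lo)) via log_ndtr in whichever tail is better
    # conditioned; fall back to the clipped probability in the bulk.
    with np.errstate(divide="ignore"):
        out = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
        # genuinely one-sided intervals get the exact log-CDF form
        out = np.where(np.isneginf(lo), log_ndtr(hi), out)
        out = np.where(np.isposinf(hi), log_ndtr(-lo), out)
    return float(np.sum(out))


def loglik_univariate(y, x, theta: ThetaUnivariate, spec: VariableSpec) -> float:
    """Dispatch to the continuous or ordinal univariate log-likelihood."""
    if spec.is_ordinal:
        return loglik_ordinal_univariate(y, x, theta, spec)
    return loglik_continuous_univariate(y, x, theta, spec)
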