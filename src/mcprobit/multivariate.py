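"""Mixed multivariate likelihood with grouped conditional dependence.

Conditioned on the outcome ``x``, the J latent responses are jointly
multivariate normal: each variable keeps its univariate mean and noise
scale, and the residuals are coupled through a correlation matrix that
does not depend on ``x``.  Correlations are shared within and between
conditional-dependence *groups* of variables, parametrized by a vector
``z``: one entry per group with at least two members (the within-group
correlation) followed by one entry per unordered pair of groups (the
between-group correlation).  With four groups of which two are
multi-member this gives 2 + 6 = 8 free terms.

The likelihood of one individual factorizes as (continuous block) x
(ordinal block | continuous block): the observed continuous values
contribute a multivariate normal density, and the ordinal stages
contribute the probability that the conditional latent vector falls in
the rectangle bounded by their thresholds.  Missing components are
marginalized, which for a multivariate normal is exactly deletion of the
corresponding rows and columns.  Setting every correlation to zero
recovers the stacked ("conditionally independent") model whose likelihood
is the pointwise product of the univariate likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from ._mvn import mvn_rectangle_probability_batch
from .data_model import (
    MixedDataset,
    ThetaMultivariate,
    ThetaUnivariate,
    ValidationError,
    VariableSpec,
)
from .response_models import _interval_prob, mean_response, noise_sd

__all__ = [
    "z_layout",
    "correlation_from_groups",
    "correlation_matrix",
    "build_covariance",
    "CovarianceAt",
    "marginalize_missing",
    "loglik_mixed_single",
    "loglik_mixed_dataset",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_PROB_FLOOR = 1e-300


def z_layout(grouping: Sequence[str]) -> tuple[list[str], list[tuple]]:
    """Canonical ordering of the correlation parameter vector.

    Returns the group labels in order of first appearance and the list of
    ``z`` slots: ``("within", g)`` for each group with >= 2 member
    variables, then ``("between", g_i, g_j)`` for each unordered pair in
    appearance order.
    """
    labels: list[str] = []
    counts: dict[str, int] = {}
    for g in grouping:
        if g not in counts:
            labels.append(g)
        counts[g] = counts.get(g, 0) + 1
    slots: list[tuple] = [("within", g) for g in labels if counts[g] >= 2]
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            slots.append(("between", gi, gj))
    return labels, slots


def within_group_correlation(group: str, grouping: Sequence[str], z) -> float:
    """The shared correlation among members of one group.

    A singleton group has no within-group parameter; asking for one is a
    structural error.
    """
    labels, slots = z_layout(grouping)
    key = ("within", group)
    if key not in slots:
        raise ValidationError(
            f"group {group!r} has fewer than two members; no within-group "
            f"correlation parameter exists"
        )
    return float(np.asarray(z, dtype=float)[slots.index(key)])


def correlation_from_groups(i: int, l: int, grouping: Sequence[str], z) -> float:
    """Correlation between variables ``i`` and ``l`` under grouped sharing."""
    if i == l:
        raise ValidationError("correlation_from_groups requires two distinct variables")
    z = np.asarray(z, dtype=float)
    labels, slots = z_layout(grouping)
    gi, gl = grouping[i], grouping[l]
    if gi == gl:
        return within_group_correlation(gi, grouping, z)
    a, b = sorted((gi, gl), key=labels.index)
    return float(z[slots.index(("between", a, b))])


def correlation_matrix(grouping: Sequence[str], z) -> np.ndarray:
    """J x J correlation matrix implied by the grouping and ``z``."""
    z = np.asarray(z, dtype=float)
    J = len(grouping)
    labels, slots = z_layout(grouping)
    if z.shape != (len(slots),):
        raise ValidationError(f"z must have length {len(slots)}, got {z.shape}")
    index = {slot: k for k, slot in enumerate(slots)}
    R = np.eye(J)
    for i in range(J):
        for l in range(i + 1, J):
            gi, gl = grouping[i], grouping[l]
            if gi == gl:
                rho = z[index[("within", gi)]]
            else:
                a, b = sorted((gi, gl), key=labels.index)
                rho = z[index[("between", a, b)]]
            R[i, l] = R[l, i] = rho
    return R


@dataclass(frozen=True)
class CovarianceAt:
    """Covariance of the latent response vector at a fixed ``x``."""

    x: float
    sigma: np.ndarray  # J x J

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.sigma))


def build_covariance(
    x: float,
    specs: Sequence[VariableSpec],
    thetas: Sequence[ThetaUnivariate],
    z,
    grouping: Sequence[str],
) -> CovarianceAt:
    """Latent covariance at ``x``: heteroscedastic diagonal, fixed correlation."""
    sds = np.array(
        [float(noise_sd(float(x), s.noise_spec, t.noise)) for s, t in zip(specs, thetas)]
    )
    R = correlation_matrix(grouping, z)
    w = np.linalg.eigvalsh(R)
    if w.min() <= 0:
        raise ValidationError(
            f"correlation matrix not positive definite (min eigenvalue {w.min():.3e})"
        )
    sigma = R * np.outer(sds, sds)
    return CovarianceAt(float(x), sigma)


def marginalize_missing(mask, specs: Sequence[VariableSpec]) -> tuple[np.ndarray, np.ndarray]:
    """Observed continuous and ordinal index sets for one individual.

    Marginalizing a missing latent component over the whole real line is
    exactly equivalent to dropping it, so the likelihood only ever sees
    these reduced index sets.
    """
    mask = np.asarray(mask, dtype=bool)
    is_ord = np.array([s.is_ordinal for s in specs])
    cont = np.where(mask & ~is_ord)[0]
    ordn = np.where(mask & is_ord)[0]
    return cont, ordn


def loglik_mixed_single(
    y,
    mask,
    x: float,
    theta: ThetaMultivariate,
    specs: Sequence[VariableSpec],
    mvn_rect_tol: float = 1e-8,
    seed: int = 0,
) -> float:
    """Log-likelihood of one individual's (possibly partial) response vector.

    Equals ``log N(w_obs; mu_C, Sigma_CC) + log P(v* in box | w_obs)``:
    observed continuous components enter through their joint normal
    density, observed ordinal components through the conditional
    multivariate normal probability of the threshold rectangle given the
    continuous values (standard Gaussian conditioning).  All-missing rows
    contribute exactly 0.  Implemented as the one-row case of
    :func:`loglik_mixed_rows`, so the dataset likelihood reduces to it
    exactly.
    """
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    data = MixedDataset(
        np.array([float(x)]), y[None, :], mask[None, :], tuple(specs)
    )
    return float(
        loglik_mixed_rows(data, theta, mvn_rect_tol=mvn_rect_tol, seed=seed)[0]
    )


def loglik_mixed_dataset(
    data: MixedDataset,
    theta: ThetaMultivariate,
    mvn_rect_tol: float = 1e-8,
    seed: int = 0,
) -> float:
    """Dataset log-likelihood: exact sum over individuals.

    Rows are grouped by missingness pattern so that the fixed per-pattern
    correlation blocks are factored once and the common cases (no ordinal
    component, a single ordinal component, or a diagonal conditional
    covariance) evaluate vectorized; per-row terms are then combined with
    an exactly rounded sum, making the total invariant to row order.
    """
    per_row = loglik_mixed_rows(data, theta, mvn_rect_tol=mvn_rect_tol, seed=seed)
    if np.any(np.isneginf(per_row)):
        return -np.inf
    return float(math.fsum(per_row.tolist()))


def loglik_mixed_rows(
    data: MixedDataset,
    theta: ThetaMultivariate,
    mvn_rect_tol: float = 1e-8,
    seed: int = 0,
) -> np.ndarray:
    """Per-individual mixed log-likelihood values (vectorized by pattern)."""
    n, J = data.Y.shape
    specs = data.specs
    R = correlation_matrix(theta.grouping, np.asarray(theta.z))
    w = np.linalg.eigvalsh(R)
    if w.min() <= 0:
        raise ValidationError(
            f"correlation matrix not positive definite (min eigenvalue {w.min():.3e})"
        )
    # per-variable standardized quantities over all rows
    mus = np.column_stack(
        [np.asarray(mean_response(data.x, theta.thetas[j], specs[j])) for j in range(J)]
    )
    sds = np.column_stack(
        [
            np.broadcast_to(
                np.asarray(noise_sd(data.x, specs[j].noise_spec, theta.thetas[j].noise)), (n,)
            )
            for j in range(J)
        ]
    )
    out = np.zeros(n)
    patterns, inverse = np.unique(data.mask, axis=0, return_inverse=True)
    for pidx, pat in enumerate(patterns):
        rows = np.where(inverse == pidx)[0]
        cont, ordn = marginalize_missing(pat, specs)
        if cont.size + ordn.size == 0:
            continue
        if cont.size:
            U = (data.Y[np.ix_(rows, cont)] - mus[np.ix_(rows, cont)]) / sds[np.ix_(rows, cont)]
            Rcc = R[np.ix_(cont, cont)]
            Lc = np.linalg.cholesky(Rcc)
            sol = np.linalg.solve(Lc, U.T).T  # (n_pat, |C|)
            out[rows] += (
                -0.5 * np.sum(sol * sol, axis=1)
                - np.sum(np.log(np.diag(Lc)))
                - np.sum(np.log(sds[np.ix_(rows, cont)]), axis=1)
                - 0.5 * cont.size * _LOG_2PI
            )
        if ordn.size:
            lo = np.empty((rows.size, ordn.size))
            hi = np.empty((rows.size, ordn.size))
            for k, j in enumerate(ordn):
                t = np.concatenate(
                    ([-np.inf], np.asarray(theta.thetas[j].tau, dtype=float), [np.inf])
                )
                v = data.Y[rows, j].astype(int)
                lo[:, k] = (t[v] - mus[rows, j]) / sds[rows, j]
                hi[:, k] = (t[v + 1] - mus[rows, j]) / sds[rows, j]
            Roo = R[np.ix_(ordn, ordn)]
            if cont.size:
                Roc = R[np.ix_(ordn, cont)]
                B = Roc @ np.linalg.inv(R[np.ix_(cont, cont)])
                cmean = U @ B.T  # (n_pat, |O|)
                ccov = Roo - B @ Roc.T
                ccov = 0.5 * (ccov + ccov.T)
            else:
                cmean = np.zeros((rows.size, ordn.size))
                ccov = Roo
            offdiag = np.max(np.abs(ccov - np.diag(np.diag(ccov)))) if ordn.size > 1 else 0.0
            if ordn.size == 1 or offdiag == 0.0:
                csd = np.sqrt(np.diag(ccov))
                probs = _interval_prob((lo - cmean) / csd, (hi - cmean) / csd)
                p = np.prod(probs, axis=1)
            else:
                cw = np.linalg.eigvalsh(ccov)
                if cw.min() <= 0:
                    raise ValidationError(
                        "conditional covariance not positive definite "
                        f"(min eigenvalue {cw.min():.3e})"
                    )
                csd = np.sqrt(np.diag(ccov))
                Rc = ccov / np.outer(csd, csd)
                p = mvn_rectangle_probability_batch(
                    (lo - cmean) / csd, (hi - cmean) / csd, Rc,
                    tol=mvn_rect_tol, seed=seed,
                )
            with np.errstate(divide="ignore"):
                out[rows] += np.where(p >= _PROB_FLOOR, np.log(np.maximum(p, _PROB_FLOOR)), -np.inf)
    return out
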