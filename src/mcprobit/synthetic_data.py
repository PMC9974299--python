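"""Generative simulator for mixed cumulative probit data.

Runs the model forward: outcomes are drawn from a prior (typically an
offset Weibull mixture, matching the age structure of a reference
skeletal sample), latent responses are multivariate normal around the
per-variable mean curves with heteroscedastic scales and the grouped
correlation structure, ordinal responses are obtained by thresholding,
and missingness is applied afterwards — either completely at random or
through deterministic observation windows in ``x`` that emulate
developmentally absent indicators (an epiphysis cannot be scored before
it appears; a diaphyseal length stops being informative once fusion
begins).

Also provides a deliberately brute-force Gauss–Legendre oracle for small
multivariate normal rectangle probabilities, used to cross-check the
production integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    MixedDataset,
    ThetaMultivariate,
    ValidationError,
    VariableSpec,
)
from .multivariate import correlation_matrix
from .prior_posterior import PriorSpec, sample_prior
from .response_models import mean_response, noise_sd

__all__ = [
    "SimulationDesign",
    "simulate_responses",
    "simulate_dataset",
    "paper_like_fixture",
    "paper_like_design",
    "oracle_rectangle_probability",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Everything needed to draw one reproducible synthetic dataset.

    ``missingness`` maps a variable name to rules: ``{"mcar": p}`` drops
    each observation independently with probability ``p``;
    ``{"window": (a, b)}`` keeps the variable observed only for
    ``a <= x <= b`` (deterministic in ``x``).  Rules combine.
    ``x_range`` optionally truncates the outcome distribution by
    rejection sampling.
    """

    theta_true: ThetaMultivariate
    specs: tuple[VariableSpec, ...]
    x_distribution: PriorSpec
    n: int
    seed: int
    missingness: Mapping[str, Mapping] = field(default_factory=dict)
    x_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for name, rules in self.missingness.items():
            if name not in [s.name for s in self.specs]:
                raise ValidationError(f"missingness rule for unknown variable {name!r}")
            if "mcar" in rules and not 0.0 <= rules["mcar"] <= 1.0:
                raise ValidationError("mcar probability must lie in [0, 1]")
            if "window" in rules:
                a, b = rules["window"]
                if a >= b:
                    raise ValidationError("window must satisfy a < b")


def simulate_responses(
    x: np.ndarray,
    theta: ThetaMultivariate,
    specs: Sequence[VariableSpec],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent and observed responses at the given outcomes.

    Returns ``(Y, latent)``: the latent matrix is multivariate normal
    with mean ``(h_j or g_j)(x)`` and covariance ``D(x) R D(x)``;
    continuous columns of ``Y`` equal the latent values and ordinal
    columns are the thresholded stages.
    """
    x = np.asarray(x, dtype=float)
    n, J = x.size, len(specs)
    R = correlation_matrix(theta.grouping, np.asarray(theta.z))
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("correlation structure is not positive definite") from exc
    E = rng.standard_normal((n, J)) @ L.T
    latent = np.empty((n, J))
    Y = np.empty((n, J))
    for j, spec in enumerate(specs):
        mu = np.asarray(mean_response(x, theta.thetas[j], spec))
        sd = np.broadcast_to(np.asarray(noise_sd(x, spec.noise_spec, theta.thetas[j].noise)), (n,))
        latent[:, j] = mu + sd * E[:, j]
        if spec.is_ordinal:
            tau = np.asarray(theta.thetas[j].tau, dtype=float)
            Y[:, j] = np.searchsorted(tau, latent[:, j], side="left")
        else:
            Y[:, j] = latent[:, j]
    return Y, latent


def simulate_dataset(design: SimulationDesign) -> MixedDataset:
    """Draw a full dataset (outcomes, responses, missingness) from a design."""
    rng = np.random.default_rng(design.seed)
    if design.x_range is None:
        x = sample_prior(design.x_distribution, design.n, rng)
    else:
        lo, hi = design.x_range
        draws: list[np.ndarray] = []
        got = 0
        while got < design.n:
            cand = sample_prior(design.x_distribution, 2 * design.n, rng)
            cand = cand[(cand >= lo) & (cand <= hi)]
            draws.append(cand)
            got += cand.size
        x = np.concatenate(draws)[: design.n]
    x = np.maximum(x, 1e-6)  # strictly positive outcomes
    Y, _ = simulate_responses(x, design.theta_true, design.specs, rng)
    mask = np.ones((design.n, len(design.specs)), dtype=bool)
    for j, spec in enumerate(design.specs):
        rules = design.missingness.get(spec.name, {})
        if "window" in rules:
            a, b = rules["window"]
            mask[:, j] &= (x >= a) & (x <= b)
        if "mcar" in rules:
            mask[:, j] &= rng.random(design.n) >= rules["mcar"]
    return MixedDataset(x, Y, mask, design.specs)


def paper_like_design(n: int = 1296) -> tuple[tuple[VariableSpec, ...], ThetaMultivariate, PriorSpec, dict]:
    """Structure of the six-variable demonstration dataset.

    Two continuous long-bone lengths (mm, power-law means with
    heteroscedastic noise growing roughly 4 to 20 across ages 0–22), an
    epiphyseal-fusion score (4 stages), an ossification count (6 stages)
    and two dental development scores (12 stages each), in four
    conditional-dependence groups (dental and long-bone pairs share
    within-group correlations) for eight free correlation terms.  The
    parameter values are arbitrary realistic constants, not estimates
    from any reference sample.
    """
    specs = (
        VariableSpec("HME_EF", "ordinal", M=3, mean_spec="pow_law",
                     noise_spec="const", group="epiphyseal_fusion"),
        VariableSpec("TC_Oss", "ordinal", M=5, mean_spec="pow_law",
                     noise_spec="const", group="ossification"),
        VariableSpec("max_M1", "ordinal", M=11, mean_spec="pow_law",
                     noise_spec="lin_pos_int", group="dental"),
        VariableSpec("man_I2", "ordinal", M=11, mean_spec="pow_law",
                     noise_spec="const", group="dental"),
        VariableSpec("FDL", "continuous", mean_spec="pow_law_offset",
                     noise_spec="lin_pos_int", group="long_bones"),
        VariableSpec("RDL", "continuous", mean_spec="pow_law_offset",
                     noise_spec="lin_pos_int", group="long_bones"),
    )
    thetas = (
        # HME_EF: fusion transitions in adolescence on the x^0.75 scale
        dict(mean=(0.75,), noise=(0.6,), tau=(5.6, 6.6, 7.4)),
        # TC_Oss: ossification completes in early childhood (sqrt-age scale)
        dict(mean=(0.5,), noise=(0.5,), tau=(0.5, 0.9, 1.3, 1.7, 2.1)),
        # dental scores: 11 thresholds spread over infancy..mid-teens
        dict(mean=(0.6,), noise=(0.35, 0.05), tau=tuple(np.linspace(0.5, 4.9, 11))),
        dict(mean=(0.6,), noise=(0.55,), tau=tuple(np.linspace(0.7, 4.5, 11))),
        # long-bone diaphyseal lengths in mm
        dict(mean=(0.85, 27.0, 70.0), noise=(4.0, 0.18)),
        dict(mean=(0.85, 14.5, 50.0), noise=(3.0, 0.15)),
    )
    from .data_model import ThetaUnivariate

    theta = ThetaMultivariate(
        thetas=tuple(ThetaUnivariate(**t) for t in thetas),
        # slots: within dental, within long_bones, then between-group pairs
        z=(0.55, 0.85, 0.30, 0.25, 0.25, 0.25, 0.25, 0.35),
        grouping=tuple(s.group for s in specs),
    )
    x_prior = PriorSpec(
        kind="weibull_mixture",
        components=((0.45, 0.8, 3.0), (0.55, 2.2, 14.0)),
    )
    missingness = {
        "HME_EF": {"window": (7.0, 22.0)},      # epiphysis scoreable once present
        "TC_Oss": {"window": (0.0, 7.0)},       # count saturates after childhood
        "max_M1": {"mcar": 0.25},
        "man_I2": {"mcar": 0.25},
        "FDL": {"mcar": 0.05},
        "RDL": {"mcar": 0.05},
    }
    return specs, theta, x_prior, missingness


def paper_like_fixture(seed: int = 0, n: int = 1296) -> MixedDataset:
    """Six-variable synthetic dataset with the demonstration structure."""
    specs, theta, x_prior, missingness = paper_like_design(n)
    design = SimulationDesign(
        theta_true=theta,
        specs=specs,
        x_distribution=x_prior,
        n=n,
        seed=seed,
        missingness=missingness,
        x_range=(0.02, 22.0),
    )
    return simulate_dataset(design)


def oracle_rectangle_probability(lower, upper, mean=None, cov=None, n_nodes: int = 80) -> float:
    """Dense tensor-product Gauss–Legendre MVN rectangle probability.

    Deliberately brute force and limited to dimension <= 3; infinite
    bounds are clipped at 8.5 standard deviations, which is negligible at
    the oracle's intended accuracy.
    """
    lower = np.atleast_1d(np.asarray(lower, dtype=float))
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    d = lower.size
    if d > 3:
        raise ValidationError("oracle supports dimension <= 3 only")
    mean = np.zeros(d) if mean is None else np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.eye(d) if cov is None else np.atleast_2d(np.asarray(cov, dtype=float))
    sd = np.sqrt(np.diag(cov))
    lo = np.where(np.isfinite(lower), lower, mean - 8.5 * sd)
    hi = np.where(np.isfinite(upper), upper, mean + 8.5 * sd)
    lo = np.minimum(np.maximum(lo, mean - 8.5 * sd), mean + 8.5 * sd)
    hi = np.minimum(np.maximum(hi, mean - 8.5 * sd), mean + 8.5 * sd)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    pts_1d, w_1d = [], []
    for k in range(d):
        a, b = lo[k], hi[k]
        pts_1d.append(0.5 * (b - a) * nodes + 0.5 * (a + b))
        w_1d.append(0.5 * (b - a) * weights)
    grids = np.meshgrid(*pts_1d, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1) - mean
    wgrid = np.meshgrid(*w_1d, indexing="ij")
    w = np.prod(np.stack([g.ravel() for g in wgrid], axis=1), axis=1)
    Lc = np.linalg.cholesky(cov)
    sol = np.linalg.solve(Lc, pts.T)
    logpdf = (
        -0.5 * np.sum(sol * sol, axis=0)
        - np.sum(np.log(np.diag(Lc)))
        - 0.5 * d * np.log(2.0 * np.pi)
    )
    return float(np.sum(w * np.exp(logpdf)))
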