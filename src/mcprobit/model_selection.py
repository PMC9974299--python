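"""Cross-validated model selection and fit diagnostics.

Model choice happens in two steps.  Step 1 picks, independently for each
variable, the mean/noise specification with the lowest summed
out-of-sample negative log-likelihood under K-fold cross-validation
(K = 4 by default), using one shared fold assignment for every variable.
Step 2 reuses the same folds to compare the conditionally independent
multivariate model (all residual correlations zero; exactly the stacked
univariate fits) against the conditionally dependent model in which the
grouped correlation vector is estimated.  The out-of-sample NLL is also
the fitting criterion, so selection and estimation share one yardstick.
AIC on the full-data fit is available as an alternative selector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CVResult,
    CVRow,
    MixedDataset,
    ThetaMultivariate,
    ValidationError,
)
from .fitting import FitError, FitOptions, fit_multivariate, fit_univariate
from .multivariate import loglik_mixed_dataset
from .response_models import loglik_univariate, stage_probabilities

__all__ = [
    "FoldAssignment",
    "assign_folds",
    "crossval_univariate",
    "apply_best_specs",
    "crossval_conditional_dependence",
    "binned_stage_proportions",
    "candidate_menu",
]


@dataclass(frozen=True)
class FoldAssignment:
    labels: np.ndarray  # fold index 0..K-1 per individual
    K: int
    seed: int

    def train_test(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.labels == k
        return ~test, test


def assign_folds(n: int, K: int = 4, seed: int = 0) -> FoldAssignment:
    """Seeded random split into K evenly sized folds (sizes differ by <= 1).

    A row keeps its fold regardless of which variables are missing there,
    so the same assignment serves every variable and both selection steps.
    """
    if n < K:
        raise ValidationError(f"need n >= K, got n={n}, K={K}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    sizes = np.full(K, n // K)
    sizes[: n % K] += 1
    start = 0
    for k, sz in enumerate(sizes):
        labels[perm[start : start + sz]] = k
        start += sz
    return FoldAssignment(labels=labels, K=K, seed=seed)


def candidate_menu(var_type: str) -> list[tuple[str, str]]:
    """Full specification menu: 3 means x 2 noises for ordinal, 1 x 2 for
    continuous."""
    noises = ["const", "lin_pos_int"]
    if var_type == "continuous":
        return [("pow_law_offset", nz) for nz in noises]
    return [(m, nz) for m in ("pow_law", "log", "lin") for nz in noises]


def _n_candidate_params(mean_spec: str, noise_spec: str) -> int:
    return {"pow_law_offset": 3, "pow_law": 1, "log": 0, "lin": 0}[mean_spec] + {
        "const": 1,
        "lin_pos_int": 2,
    }[noise_spec]


def crossval_univariate(
    data: MixedDataset,
    variable: str,
    candidates: Sequence[tuple[str, str]] | None = None,
    folds: FoldAssignment | None = None,
    options: FitOptions = FitOptions(),
    selector: str = "cv",
) -> CVResult:
    """Step-1 selection of one variable's mean/noise specification.

    For each candidate, fits on every training fold and sums the negative
    log-likelihood of the held-out rows where the variable is observed.
    Candidates that fail to fit on any fold are recorded as
    ``rejected_fit_failure``; candidates whose fitted noise slope exceeds
    the configured ceiling on any fold as ``rejected_large_noise_slope``.
    Ties in the summed NLL break toward the model with fewer parameters,
    then candidate order.
    """
    j = data.column(variable)
    spec = data.specs[j]
    if candidates is None:
        candidates = candidate_menu(spec.var_type)
    if not candidates:
        raise ValidationError("candidate list must be nonempty")
    if folds is None:
        folds = assign_folds(data.n, 4, options.seed)
    result = CVResult()
    for mean_spec, noise_spec in candidates:
        cand_spec = spec.with_candidates(mean_spec, noise_spec)
        status, eta = "ok", 0.0
        if selector == "aic":
            try:
                rep = fit_univariate(data, variable, mean_spec, noise_spec, options)
            except FitError:
                status, eta = "rejected_fit_failure", None
            else:
                if rep.large_noise_slope:
                    status, eta = "rejected_large_noise_slope", None
                else:
                    k = _n_candidate_params(mean_spec, noise_spec) + (spec.M or 0)
                    eta = 2.0 * k + 2.0 * rep.nll_final
        else:
            for k in range(folds.K):
                train, test = folds.train_test(k)
                try:
                    rep = fit_univariate(
                        data.subset_rows(train), variable, mean_spec, noise_spec, options
                    )
                except FitError:
                    status, eta = "rejected_fit_failure", None
                    break
                if rep.large_noise_slope:
                    status, eta = "rejected_large_noise_slope", None
                    break
                ds_test = data.subset_rows(test)
                x_t, y_t = ds_test.observed(variable)
                eta += -loglik_univariate(y_t, x_t, rep.theta_hat, cand_spec)
            if status == "ok" and not np.isfinite(eta):
                status, eta = "rejected_fit_failure", None
        result.rows.append(CVRow(variable, mean_spec, noise_spec, status, eta))
    return result


def apply_best_specs(data: MixedDataset, cv: CVResult) -> MixedDataset:
    """Dataset copy whose specs carry each variable's CV-preferred candidate."""
    new_specs = []
    for spec in data.specs:
        mine = [r for r in cv.rows if r.variable == spec.name and r.status == "ok"]
        if mine:
            best = min(
                mine,
                key=lambda r: (r.nll, _n_candidate_params(r.mean_spec, r.noise_spec)),
            )
            spec = spec.with_candidates(best.mean_spec, best.noise_spec)
        new_specs.append(spec)
    return replace_specs(data, new_specs)


def replace_specs(data: MixedDataset, specs) -> MixedDataset:
    return MixedDataset(data.x, data.Y, data.mask, tuple(specs))


def crossval_conditional_dependence(
    data: MixedDataset,
    grouping: Sequence[str] | None = None,
    folds: FoldAssignment | None = None,
    options: FitOptions = FitOptions(),
    fit_z_only: bool = False,
) -> tuple[float, float, str]:
    """Step-2 comparison of conditional independence vs dependence.

    Per fold, fits every variable univariately on the training rows,
    evaluates the held-out NLL of the stacked (z = 0) model, then fits the
    conditionally dependent model (initialized at the stacked fits) and
    evaluates its held-out NLL.  Returns ``(eta_ci, eta_cd, preferred)``
    where preferred is the model with the smaller summed NLL.

    The dataset's specs must already carry the Step-1 winners.
    """
    if folds is None:
        folds = assign_folds(data.n, 4, options.seed)
    grouping = tuple(grouping if grouping is not None else (s.group for s in data.specs))
    from .data_model import n_correlation_terms

    n_z = n_correlation_terms(grouping)
    eta_ci = eta_cd = 0.0
    for k in range(folds.K):
        train, test = folds.train_test(k)
        ds_train = data.subset_rows(train)
        ds_test = data.subset_rows(test)
        uni = [
            fit_univariate(ds_train, s.name, options=options).theta_hat for s in data.specs
        ]
        theta_ci = ThetaMultivariate(thetas=tuple(uni), z=(0.0,) * n_z, grouping=grouping)
        eta_ci += -loglik_mixed_dataset(
            ds_test, theta_ci, mvn_rect_tol=options.mvn_rect_tol, seed=options.seed
        )
        rep = fit_multivariate(ds_train, uni, grouping, options, fit_z_only=fit_z_only)
        eta_cd += -loglik_mixed_dataset(
            ds_test, rep.theta_hat, mvn_rect_tol=options.mvn_rect_tol, seed=options.seed
        )
    preferred = "conditionally_dependent" if eta_cd < eta_ci else "conditionally_independent"
    return float(eta_ci), float(eta_cd), preferred


def binned_stage_proportions(
    data: MixedDataset,
    variable: str,
    stage: int,
    theta,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Observed vs predicted probability of one ordinal stage across x-bins.

    Observed rows are split into ``n_bins`` equal-count bins by ``x``; the
    empirical proportion of ``v == stage`` in each bin sits next to the
    model's stage probability at the bin's mean ``x``.  Useful as a visual
    goodness-of-fit check for a single stage's probability curve.
    """
    j = data.column(variable)
    spec = data.specs[j]
    if not spec.is_ordinal:
        raise ValidationError("binned stage proportions require an ordinal variable")
    x, v = data.observed(variable)
    if x.size < n_bins:
        raise ValidationError("fewer observed rows than bins")
    order = np.argsort(x, kind="stable")
    x, v = x[order], v[order]
    splits = np.array_split(np.arange(x.size), n_bins)
    rows = []
    for idx in splits:
        xb = float(np.mean(x[idx]))
        obs = float(np.mean(v[idx] == stage))
        model = float(stage_probabilities(xb, theta, spec)[stage])
        rows.append((xb, obs, model))
    return pd.DataFrame(rows, columns=["bin_center", "observed_proportion", "model_probability"])
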