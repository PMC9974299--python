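"""Domain types, dataset validation, and model serialization.

The mixed cumulative probit (MCP) models a single positive continuous
outcome ``x`` (age, in the motivating application) through a set of J
response variables, each either continuous (e.g. a diaphyseal length in
mm) or ordinal (a developmental stage in ``0..M``).  Every response has a
latent Gaussian representation whose mean and standard deviation are
parametric functions of ``x``; ordinal responses are observed through
ordered thresholds.  The types below carry variable declarations, fitted
parameter blocks, datasets with an explicit missingness mask, and density
grids for prior/posterior inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "ThetaUnivariate",
    "ThetaMultivariate",
    "MixedDataset",
    "DensityGrid",
    "CVRow",
    "CVResult",
    "ValidationError",
    "load_dataset",
    "save_model",
    "load_model",
    "n_correlation_terms",
]

SCHEMA_VERSION = 1

CONTINUOUS_MEAN_SPECS = ("pow_law_offset",)
ORDINAL_MEAN_SPECS = ("pow_law", "log", "lin")
NOISE_SPECS = ("const", "lin_pos_int")


class ValidationError(ValueError):
    """Raised when input data or a configuration violates an invariant."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one response variable.

    Parameters
    ----------
    name
        Column name in the data table.
    var_type
        ``"continuous"`` or ``"ordinal"``.
    M
        Highest ordinal stage; stages are coded ``0..M`` (ordinal only).
    mean_spec
        Mean response: ``pow_law_offset`` (continuous, ``c2*x^c1 + c3``) or
        one of ``pow_law`` (``x^b1``), ``log``, ``lin`` for ordinal
        variables.  Ordinal means carry no scale or offset; the thresholds
        absorb location/scale, which keeps the model identifiable.
    noise_spec
        ``const`` (homoscedastic, sd ``k1``) or ``lin_pos_int``
        (heteroscedastic, sd ``k1*(1 + k2*x)`` with a positive intercept).
    group
        Conditional-dependence group label (variables sharing residual
        correlation behaviour).
    recode
        Optional map applied to raw ordinal codes before range validation,
        e.g. collapsing a 7-stage scoring system to 4 stages.
    """

    name: str
    var_type: str
    M: int | None = None
    mean_spec: str | None = None
    noise_spec: str = "const"
    group: str = "default"
    recode: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.var_type not in ("continuous", "ordinal"):
            raise ValidationError(f"unknown var_type {self.var_type!r}")
        if self.mean_spec is None:
            object.__setattr__(
                self,
                "mean_spec",
                "pow_law_offset" if self.var_type == "continuous" else "pow_law",
            )
        if self.var_type == "continuous":
            if self.mean_spec not in CONTINUOUS_MEAN_SPECS:
                raise ValidationError(
                    f"{self.name}: continuous mean_spec must be one of "
                    f"{CONTINUOUS_MEAN_SPECS}, got {self.mean_spec!r}"
                )
            if self.M is not None:
                raise ValidationError(f"{self.name}: continuous variable must not set M")
        else:
            if self.M is None or self.M < 1:
                raise ValidationError(f"{self.name}: ordinal variable needs M >= 1")
            if self.mean_spec not in ORDINAL_MEAN_SPECS:
                raise ValidationError(
                    f"{self.name}: ordinal mean_spec must be one of "
                    f"{ORDINAL_MEAN_SPECS}, got {self.mean_spec!r}"
                )
        if self.noise_spec not in NOISE_SPECS:
            raise ValidationError(f"{self.name}: unknown noise_spec {self.noise_spec!r}")

    @property
    def is_ordinal(self) -> bool:
        return self.var_type == "ordinal"

    def with_candidates(self, mean_spec: str, noise_spec: str) -> "VariableSpec":
        """Copy of this spec with a different mean/noise candidate."""
        return replace(self, mean_spec=mean_spec, noise_spec=noise_spec)


def _as_tuple(v) -> tuple[float, ...]:
    if v is None:
        return ()
    return tuple(float(x) for x in np.atleast_1d(v))


@dataclass(frozen=True)
class ThetaUnivariate:
    """Fitted parameter block for one response variable.

    ``mean`` holds ``(c1, c2, c3)`` for a continuous variable (all > 0),
    ``(b1,)`` for an ordinal power-law mean, and is empty for the
    parameter-free ``log``/``lin`` means.  ``noise`` holds ``(k1,)`` for
    constant noise or ``(k1, k2)`` for the linear-positive-intercept model
    (the ordinal noise parameters share this structure).  ``tau`` holds the
    strictly increasing thresholds of an ordinal variable.
    """

    mean: tuple[float, ...] = ()
    noise: tuple[float, ...] = (1.0,)
    tau: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", _as_tuple(self.mean))
        object.__setattr__(self, "noise", _as_tuple(self.noise))
        object.__setattr__(self, "tau", _as_tuple(self.tau))
        if any(k <= 0 for k in self.noise):
            raise ValidationError(f"noise parameters must be positive, got {self.noise}")
        if len(self.tau) > 1 and not np.all(np.diff(self.tau) > 0):
            raise ValidationError(f"thresholds must be strictly increasing, got {self.tau}")

    def to_dict(self) -> dict:
        return {"mean": list(self.mean), "noise": list(self.noise), "tau": list(self.tau)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThetaUnivariate":
        return cls(mean=tuple(d["mean"]), noise=tuple(d["noise"]), tau=tuple(d["tau"]))


def n_correlation_terms(groups: Sequence[str]) -> int:
    """Number of free correlation parameters under grouped sharing.

    One term per unordered pair of distinct groups, plus one within-group
    term per group with at least two member variables.  For four groups of
    which two have two members this gives 6 + 2 = 8.
    """
    labels: list[str] = []
    counts: dict[str, int] = {}
    for g in groups:
        if g not in counts:
            labels.append(g)
        counts[g] = counts.get(g, 0) + 1
    n_groups = len(labels)
    n_between = n_groups * (n_groups - 1) // 2
    n_within = sum(1 for g in labels if counts[g] >= 2)
    return n_between + n_within


@dataclass(frozen=True)
class ThetaMultivariate:
    """All univariate parameter blocks plus the grouped correlation vector.

    ``z`` stacks the within-group terms (groups with >= 2 members, in
    order of first appearance in ``grouping``) followed by between-group
    terms (unordered group pairs in appearance order).  Each entry lies in
    (-1, 1); the implied correlation matrix must be positive definite,
    which is checked at construction for the grouped structure.
    """

    thetas: tuple[ThetaUnivariate, ...]
    z: tuple[float, ...]
    grouping: tuple[str, ...]  # group label per variable, in variable order

    def __post_init__(self) -> None:
        object.__setattr__(self, "thetas", tuple(self.thetas))
        object.__setattr__(self, "z", _as_tuple(self.z))
        object.__setattr__(self, "grouping", tuple(self.grouping))
        if len(self.grouping) != len(self.thetas):
            raise ValidationError("grouping must give one label per variable")
        expect = n_correlation_terms(self.grouping)
        if len(self.z) != expect:
            raise ValidationError(
                f"z has length {len(self.z)}, grouping requires {expect}"
            )
        if any(abs(v) >= 1 for v in self.z):
            raise ValidationError("correlation parameters must lie in (-1, 1)")
        # defer to multivariate.correlation_matrix for the PD check
        from . import multivariate as _mv

        R = _mv.correlation_matrix(self.grouping, np.asarray(self.z))
        w = np.linalg.eigvalsh(R)
        if w.min() <= 0:
            raise ValidationError(
                f"implied correlation matrix not positive definite "
                f"(min eigenvalue {w.min():.3e})"
            )

    def to_dict(self) -> dict:
        return {
            "thetas": [t.to_dict() for t in self.thetas],
            "z": list(self.z),
            "grouping": list(self.grouping),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThetaMultivariate":
        return cls(
            thetas=tuple(ThetaUnivariate.from_dict(t) for t in d["thetas"]),
            z=tuple(d["z"]),
            grouping=tuple(d["grouping"]),
        )


@dataclass
class MixedDataset:
    """n individuals x J responses with an explicit missingness mask.

    ``Y`` is a float matrix; ordinal columns hold integer-valued stages.
    ``mask[i, j]`` is True where ``Y[i, j]`` was observed.  Missingness is
    a mask rather than a sentinel so that stage 0 ("absent") remains a
    valid, informative observation.
    """

    x: np.ndarray
    Y: np.ndarray
    mask: np.ndarray
    specs: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.specs = tuple(self.specs)
        n, J = self.Y.shape
        if self.x.shape != (n,) or self.mask.shape != (n, J) or len(self.specs) != J:
            raise ValidationError("inconsistent dataset shapes")
        if np.any(self.x <= 0):
            i = int(np.argmax(self.x <= 0))
            raise ValidationError(f"x must be strictly positive (row {i}: x={self.x[i]})")
        for j, spec in enumerate(self.specs):
            if spec.is_ordinal:
                obs = self.Y[self.mask[:, j], j]
                if obs.size and (np.any(obs != np.round(obs)) or obs.min() < 0 or obs.max() > spec.M):
                    bad = np.where(
                        self.mask[:, j]
                        & ((self.Y[:, j] != np.round(self.Y[:, j]))
                           | (self.Y[:, j] < 0) | (self.Y[:, j] > spec.M))
                    )[0][0]
                    raise ValidationError(
                        f"column {spec.name!r}, row {int(bad)}: ordinal value "
                        f"{self.Y[bad, j]} outside 0..{spec.M}"
                    )

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def J(self) -> int:
        return self.Y.shape[1]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def column(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown variable {name!r}") from None

    def observed(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) restricted to rows where ``name`` is observed."""
        j = self.column(name)
        m = self.mask[:, j]
        return self.x[m], self.Y[m, j]

    def subset_rows(self, idx: np.ndarray) -> "MixedDataset":
        return MixedDataset(self.x[idx], self.Y[idx], self.mask[idx], self.specs)

    def subset_variables(self, names: Sequence[str]) -> "MixedDataset":
        cols = [self.column(nm) for nm in names]
        return MixedDataset(
            self.x, self.Y[:, cols], self.mask[:, cols],
            tuple(self.specs[c] for c in cols),
        )

    def to_frame(self, x_col: str = "x") -> pd.DataFrame:
        df = pd.DataFrame({x_col: self.x})
        for j, spec in enumerate(self.specs):
            col = self.Y[:, j].astype(object)
            col[~self.mask[:, j]] = np.nan
            df[spec.name] = col
        return df


@dataclass
class DensityGrid:
    """A density over the outcome, tabulated on a strictly increasing grid."""

    x_calc: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.x_calc = np.asarray(self.x_calc, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.x_calc.ndim != 1 or self.x_calc.shape != self.f.shape:
            raise ValidationError("x_calc and f must be 1-D of equal length")
        if np.any(np.diff(self.x_calc) <= 0):
            raise ValidationError("x_calc must be strictly increasing")
        if np.any(self.f < 0):
            raise ValidationError("density values must be nonnegative")

    def normalize(self) -> "DensityGrid":
        Z = np.trapezoid(self.f, self.x_calc)
        if Z <= 0:
            raise ValidationError("cannot normalize a zero density")
        return DensityGrid(self.x_calc, self.f / Z)

    def integral(self) -> float:
        return float(np.trapezoid(self.f, self.x_calc))


@dataclass(frozen=True)
class CVRow:
    variable: str
    mean_spec: str
    noise_spec: str
    status: str  # ok | rejected_fit_failure | rejected_large_noise_slope
    nll: float | None  # summed out-of-sample negative log-likelihood


@dataclass
class CVResult:
    """Cross-validation table for one or more variables."""

    rows: list[CVRow] = field(default_factory=list)

    def best(self, variable: str) -> CVRow:
        ok = [r for r in self.rows if r.variable == variable and r.status == "ok"]
        if not ok:
            raise ValidationError(f"no successfully fitted candidate for {variable!r}")
        return min(ok, key=lambda r: r.nll)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.variable, r.mean_spec, r.noise_spec, r.status, r.nll) for r in self.rows],
            columns=["variable", "mean_spec", "noise_spec", "status", "nll"],
        )


# ---------------------------------------------------------------------------
# I/O


def load_dataset(
    path,
    specs: Sequence[VariableSpec],
    x_col: str = "x",
) -> MixedDataset:
    """Read a CSV of individuals into a validated :class:`MixedDataset`.

    The file needs a positive ``x_col`` column and one column per declared
    variable; empty cells and the usual NA spellings are treated as
    missing.  A spec's ``recode`` map is applied to the raw (string) codes
    of its ordinal column before range validation, which is how collapsed
    stage systems (e.g. a 7-stage fusion score recorded as
    ``0,1,1/2,2,2/3,3,4`` collapsed to 4 stages) enter the pipeline.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    df.columns = [c.strip() for c in df.columns]
    if x_col not in df.columns:
        raise ValidationError(f"missing x column {x_col!r}")
    for spec in specs:
        if spec.name not in df.columns:
            raise ValidationError(f"unknown column {spec.name!r} (not in file)")
    x = pd.to_numeric(df[x_col], errors="raise").to_numpy(dtype=float)
    n = len(df)
    J = len(specs)
    Y = np.zeros((n, J))
    mask = np.zeros((n, J), dtype=bool)
    for j, spec in enumerate(specs):
        raw = df[spec.name]
        obs = raw.notna() & (raw.astype(str).str.strip() != "")
        mask[:, j] = obs.to_numpy()
        vals = raw[obs].astype(str).str.strip()
        if spec.recode:
            recode = {str(k).strip(): v for k, v in spec.recode.items()}
            vals = vals.map(lambda s: recode.get(s, s))
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise ValidationError(
                f"column {spec.name!r}, row {row}: value {raw.iloc[row]!r} is not "
                f"numeric after recode"
            )
        Y[mask[:, j], j] = numeric.to_numpy(dtype=float)
    return MixedDataset(x, Y, mask, tuple(specs))


def save_model(theta: ThetaUnivariate | ThetaMultivariate, path) -> None:
    """Serialize a fitted parameter object to JSON (full float precision)."""
    kind = "multivariate" if isinstance(theta, ThetaMultivariate) else "univariate"
    payload = {"schema_version": SCHEMA_VERSION, "kind": kind, "theta": theta.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> ThetaUnivariate | ThetaMultivariate:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"model schema version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    d = payload["theta"]
    if payload["kind"] == "multivariate":
        return ThetaMultivariate.from_dict(d)
    for key in ("mean", "noise", "tau"):
        if key not in d:
            raise ValidationError(f"model file missing field {key!r}")
    return ThetaUnivariate.from_dict(d)
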