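"""Kernel functions over gene expression profiles.

Four kernel families measure similarity between two genes' expression
profiles x and y:

    linear      k(x, y) = x.y + c
    polynomial  k(x, y) = (alpha * x.y + c) ** d
    gaussian    k(x, y) = exp(-gamma * ||x - y||^2)
    sigmoid     k(x, y) = tanh(alpha * x.y + c)

Profiles are standardized gene-wise (zero mean, unit sample standard
deviation) before any kernel evaluation, so hyperparameter grids transfer
across compendia measured in different units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .data import ExpressionMatrix

__all__ = [
    "KERNEL_FAMILIES",
    "KernelSpec",
    "KernelOverflowError",
    "kernel_value",
    "gram_matrix",
    "standardize_profiles",
    "default_grid",
]

KERNEL_FAMILIES = ("linear", "polynomial", "gaussian", "sigmoid")


class KernelOverflowError(FloatingPointError):
    """A kernel evaluation produced a non-finite value (polynomial blow-up)."""


@dataclass(frozen=True)
class KernelSpec:
    """One kernel family with its hyperparameters.

    Parameters irrelevant to the family are stored but ignored.  ``gamma``
    may be ``None``, meaning "resolve to 1 / n_features at evaluation time"
    (the usual scale heuristic); ``C`` is the soft-margin complexity
    parameter of the classifier, not of the kernel itself, and rides along
    here because grid search tunes it jointly.
    """

    family: str = "gaussian"
    c: float = 0.0
    alpha: float = 1.0
    d: int = 2
    gamma: float | None = None
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.gamma is not None and not self.gamma > 0:
            raise ValueError("gamma must be positive (or None for 1/n_features)")
        if int(self.d) < 1 or int(self.d) != self.d:
            raise ValueError("polynomial degree d must be a positive integer")
        if not self.C > 0:
            raise ValueError("complexity parameter C must be positive")

    def resolved(self, n_features: int) -> "KernelSpec":
        """Concrete spec with gamma=None replaced by 1/n_features."""
        if self.gamma is not None:
            return self
        return replace(self, gamma=1.0 / n_features)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "c": self.c,
            "alpha": self.alpha,
            "d": int(self.d),
            "gamma": self.gamma,
            "C": self.C,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "KernelSpec":
        return cls(**{k: payload[k] for k in ("family", "c", "alpha", "d", "gamma", "C") if k in payload})


def gram_matrix(spec: KernelSpec, X, Y) -> np.ndarray:
    """Kernel matrix K with K[i, j] = k(X[i], Y[j]).

    ``X`` and ``Y`` are 2-D arrays whose rows are profiles of equal length.
    Raises :class:`KernelOverflowError` if any entry is non-finite, so a
    grid search can skip the offending hyperparameter point explicitly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"profile length mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if X.shape[1] < 1:
        raise ValueError("profiles must have at least one experiment")
    spec = spec.resolved(X.shape[1])
    if spec.family == "linear":
        K = X @ Y.T + spec.c
    elif spec.family == "polynomial":
        with np.errstate(over="ignore"):
            K = (spec.alpha * (X @ Y.T) + spec.c) ** int(spec.d)
    elif spec.family == "gaussian":
        K = np.exp(-spec.gamma * cdist(X, Y, "sqeuclidean"))
    else:  # sigmoid
        K = np.tanh(spec.alpha * (X @ Y.T) + spec.c)
    if not np.all(np.isfinite(K)):
        i, j = np.argwhere(~np.isfinite(K))[0]
        raise KernelOverflowError(
            f"non-finite {spec.family} kernel value for profile pair ({i}, {j}) "
            f"with parameters alpha={spec.alpha}, c={spec.c}, d={spec.d}"
        )
    return K


def kernel_value(spec: KernelSpec, x, y) -> float:
    """Kernel evaluated on a single pair of profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("kernel_value expects 1-D profiles")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"profile length mismatch: {x.shape[0]} vs {y.shape[0]}")
    return float(gram_matrix(spec, x[None, :], y[None, :])[0, 0])


def standardize_profiles(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to zero mean, unit sample (ddof=1) sd.

    Constant rows map to all-zeros rather than dividing by zero.
    """
    if matrix.n_experiments < 2:
        raise ValueError("standardization needs at least 2 experiments per gene")
    values = matrix.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    safe_sd = np.where(sd > 0, sd, 1.0)
    out = (values - mean) / safe_sd
    out[np.ravel(sd == 0)] = 0.0
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.experiment_ids), out)


# Default hyperparameter grids.  Every non-linear family tunes C plus one
# kernel parameter; the linear kernel tunes C alone.
_C_GRID = tuple(2.0 ** k for k in range(-5, 10, 2))          # 2^-5 .. 2^9
_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))      # 2^-15 .. 2^3
_DEGREE_GRID = (2, 3, 4)
_ALPHA_GRID = tuple(2.0 ** k for k in range(-8, 1))          # 2^-8 .. 2^0


def default_grid(family: str) -> list[KernelSpec]:
    """The default grid-search points for one kernel family."""
    if family == "linear":
        return [KernelSpec("linear", c=0.0, C=C) for C in _C_GRID]
    if family == "gaussian":
        return [
            KernelSpec("gaussian", gamma=g, C=C)
            for C, g in itertools.product(_C_GRID, _GAMMA_GRID)
        ]
    if family == "polynomial":
        return [
            KernelSpec("polynomial", alpha=1.0, c=1.0, d=d, C=C)
            for C, d in itertools.product(_C_GRID, _DEGREE_GRID)
        ]
    if family == "sigmoid":
        return [
            KernelSpec("sigmoid", alpha=a, c=0.0, C=C)
            for C, a in itertools.product(_C_GRID, _ALPHA_GRID)
        ]
    raise ValueError(f"unknown kernel family {family!r}")
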