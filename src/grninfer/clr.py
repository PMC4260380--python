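"""Context likelihood of relatedness (CLR): the unsupervised baseline.

Pairwise mutual information is estimated from correlation under a Gaussian
assumption, MI = -1/2 ln(1 - rho^2), with Pearson or Spearman correlation.
Each gene's off-diagonal MI values form its background distribution; an MI
value is converted to a z-score against both genes' backgrounds (negative
z clamped to zero) and the two are combined as sqrt(z_i^2 + z_j^2).  The
resulting symmetric relevance matrix is projected onto directed (TF, gene)
candidate pairs for ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import EdgeScoreTable, ExpressionMatrix

__all__ = [
    "MIMatrix",
    "CLRScoreTable",
    "mi_from_correlation",
    "mi_matrix",
    "clr_scores",
    "clr_edge_table",
]

logger = logging.getLogger(__name__)

# rho^2 is clamped just below 1 so perfectly correlated (e.g. duplicated)
# simulated genes keep a finite, maximal MI.
_RHO_SQ_CEILING = 1.0 - 1e-12
MI_CEILING = -0.5 * math.log1p(-_RHO_SQ_CEILING)


def _check_symmetric_nonneg(gene_ids, values, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(gene_ids)
    if values.shape != (n, n):
        raise ValueError(f"{what} must be {n}x{n}")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError(f"{what} must be symmetric")
    if np.any(np.diag(values) != 0):
        raise ValueError(f"{what} must have a zero diagonal")
    if np.any(values < 0):
        raise ValueError(f"{what} entries must be non-negative")
    return values


@dataclass
class MIMatrix:
    """Symmetric non-negative mutual-information matrix, zero diagonal."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_symmetric_nonneg(self.gene_ids, self.values, "MI matrix")


@dataclass
class CLRScoreTable:
    """Symmetric combined z-score matrix, zero diagonal, entries >= 0."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_symmetric_nonneg(self.gene_ids, self.values, "CLR score matrix")


def mi_from_correlation(rho: float) -> float:
    """Gaussian mutual information -1/2 ln(1 - rho^2) of a correlation."""
    if abs(rho) > 1:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    rho_sq = min(rho * rho, _RHO_SQ_CEILING)
    return -0.5 * math.log1p(-rho_sq)


def mi_matrix(expression: ExpressionMatrix, method: str = "pearson") -> MIMatrix:
    """Pairwise correlation-based MI over all gene pairs.

    ``method`` is ``pearson`` (product-moment) or ``spearman`` (average-rank
    based).  Constant gene rows have undefined correlation; their MI is set
    to 0 with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    if expression.n_experiments < 3:
        raise ValueError("MI estimation needs at least 3 experiments")
    X = expression.values
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)  # average ranks for ties
    sd = X.std(axis=1, ddof=1)
    constant = sd == 0
    if np.any(constant):
        logger.warning(
            "constant expression rows (MI set to 0): %s",
            [g for g, c in zip(expression.gene_ids, constant) if c],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(X)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    rho = np.clip(rho, -1.0, 1.0)
    rho_sq = np.minimum(rho * rho, _RHO_SQ_CEILING)
    mi = -0.5 * np.log1p(-rho_sq)
    np.fill_diagonal(mi, 0.0)
    mi = 0.5 * (mi + mi.T)  # enforce exact symmetry against fp asymmetry
    return MIMatrix(list(expression.gene_ids), mi)


def clr_scores(mi: MIMatrix) -> CLRScoreTable:
    """Adaptive background correction and z-score combination.

    Gene i's background is its off-diagonal MI row; with mean mu_i and
    sample (ddof=1) sd sigma_i, z_i(j) = max(0, (MI_ij - mu_i) / sigma_i)
    (zero when sigma_i = 0), and the combined symmetric score is
    sqrt(z_i(j)^2 + z_j(i)^2).
    """
    n = len(mi.gene_ids)
    if n < 3:
        raise ValueError("CLR background needs at least 3 genes")
    M = mi.values
    off = ~np.eye(n, dtype=bool)
    backgrounds = M[off].reshape(n, n - 1)
    mu = backgrounds.mean(axis=1)
    sigma = backgrounds.std(axis=1, ddof=1)
    safe_sigma = np.where(sigma > 0, sigma, 1.0)
    z_rows = (M - mu[:, None]) / safe_sigma[:, None]   # z_i(j) in row i
    z_rows = np.clip(z_rows, 0.0, None)
    z_rows[sigma == 0, :] = 0.0
    combined = np.sqrt(z_rows**2 + z_rows.T**2)
    np.fill_diagonal(combined, 0.0)
    return CLRScoreTable(list(mi.gene_ids), combined)


def clr_edge_table(scores: CLRScoreTable, tfs: list[str]) -> EdgeScoreTable:
    """Project the symmetric score matrix onto directed (tf, gene) pairs."""
    index = {g: i for i, g in enumerate(scores.gene_ids)}
    missing = [tf for tf in tfs if tf not in index]
    if missing:
        raise KeyError(f"TFs not in score table: {missing}")
    entries = [
        (tf, g, float(scores.values[index[tf], index[g]]))
        for tf in tfs
        for g in scores.gene_ids
        if g != tf
    ]
    return EdgeScoreTable(entries)
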