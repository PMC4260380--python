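"""Supervised network inference with one local kernel classifier per TF.

For each transcription factor a soft-margin SVM is trained to separate its
known targets (positives) from all other genes (closed-world negatives),
using the genes' standardized expression profiles as features.  The trained
model scores any gene x as

    f(x) = sum_i w_i * K(x_i, x) + b

where the x_i are the support profiles, the w_i are the signed dual weights
(bounded by the complexity parameter C) and b is the learned bias.  Raw
decision values from all local models are pooled into one ranked candidate
edge table; hyperparameters are chosen by grid search under per-TF
stratified cross-validation with held-out scores pooled into a single AUC.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import EdgeScoreTable, ExpressionMatrix, LabelSet, RegulatoryNetwork, build_labels
from .kernels import KernelOverflowError, KernelSpec, gram_matrix, standardize_profiles

__all__ = [
    "UntrainableTFError",
    "LocalModel",
    "GridSearchResult",
    "train_local_model",
    "score_genes",
    "infer_network",
    "grid_search",
    "pooled_cv_scores",
]

logger = logging.getLogger(__name__)

SENTINEL_SCORE = float("-inf")


def _normalize_scores(scores: np.ndarray, score_norm: str) -> np.ndarray:
    """Optionally rank-normalize one local model's scores to [0, 1].

    ``none`` pools raw decision values (the default); ``rank`` replaces
    them by within-model fractional ranks, making models with different
    decision-value scales comparable before pooling.
    """
    if score_norm == "none":
        return scores
    if score_norm == "rank":
        from scipy.stats import rankdata

        return rankdata(scores) / len(scores)
    raise ValueError(f"score_norm must be 'none' or 'rank', got {score_norm!r}")


class UntrainableTFError(ValueError):
    """Raised when a TF has no positive or no negative training examples."""

    def __init__(self, tf: str, reason: str):
        self.tf = tf
        super().__init__(f"TF {tf!r} is untrainable: {reason}")


@dataclass
class LocalModel:
    """One TF's trained classifier in explicit dual form."""

    tf: str
    spec: KernelSpec
    support_profiles: np.ndarray          # rows = standardized support profiles x_i
    weights: np.ndarray                   # signed dual weights, |w_i| <= C
    bias: float
    training_gene_ids: list[str]          # gene ids of the support profiles

    def __post_init__(self) -> None:
        self.support_profiles = np.asarray(self.support_profiles, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.support_profiles.shape[0] != self.weights.shape[0]:
            raise ValueError("one weight per support profile required")
        if abs(self.weights.sum()) > 1e-6:
            raise ValueError("signed dual weights must sum to zero")
        if np.any(np.abs(self.weights) > self.spec.C + 1e-9):
            raise ValueError("dual weights must be bounded by C")

    def decision_values(self, profiles: np.ndarray) -> np.ndarray:
        """f(x) = sum_i w_i K(x_i, x) + b for each query profile row."""
        K = gram_matrix(self.spec, self.support_profiles, np.atleast_2d(profiles))
        return self.weights @ K + self.bias


@dataclass
class GridSearchResult:
    best_spec: KernelSpec
    cv_auc_by_point: dict[KernelSpec, float]
    folds: int


def _fit_dual(K: np.ndarray, y: np.ndarray, spec: KernelSpec, class_weight=None):
    """Fit libsvm on a precomputed Gram matrix; return (support idx, weights, bias).

    ``y`` must be +/-1.  sklearn orders classes [-1, +1], so its decision
    function is already positive for the +1 class.
    """
    svc = SVC(C=spec.C, kernel="precomputed", class_weight=class_weight)
    svc.fit(K, y)
    return svc.support_.copy(), svc.dual_coef_[0].copy(), float(svc.intercept_[0]), svc


def train_local_model(
    expression: ExpressionMatrix,
    labels: LabelSet,
    spec: KernelSpec,
    class_weight: str | None = None,
) -> LocalModel:
    """Train one TF's soft-margin kernel classifier.

    Profiles are standardized gene-wise before the Gram matrix is formed.
    Deterministic given identical inputs (libsvm's SMO solver has no
    randomness for a fixed problem).
    """
    if not labels.positives:
        raise UntrainableTFError(labels.tf, "no positive examples")
    if not labels.negatives:
        raise UntrainableTFError(labels.tf, "no negative examples")
    genes = sorted(labels.positives) + sorted(labels.negatives)
    missing = [g for g in genes if g not in expression]
    if missing:
        raise KeyError(f"labeled genes missing from expression matrix: {missing}")
    std = standardize_profiles(expression)
    X = std.rows(genes)
    y = np.array([1 if g in labels.positives else -1 for g in genes])
    spec = spec.resolved(X.shape[1])
    K = gram_matrix(spec, X, X)
    support, weights, bias, _ = _fit_dual(K, y, spec, class_weight)
    return LocalModel(
        tf=labels.tf,
        spec=spec,
        support_profiles=X[support],
        weights=weights,
        bias=bias,
        training_gene_ids=[genes[i] for i in support],
    )


def score_genes(
    model: LocalModel, expression: ExpressionMatrix, candidate_genes: list[str]
) -> EdgeScoreTable:
    """Score candidate targets of ``model.tf`` with raw decision values."""
    if model.tf in candidate_genes:
        raise ValueError(f"TF {model.tf!r} cannot be its own candidate target")
    std = standardize_profiles(expression)
    profiles = std.rows(list(candidate_genes))
    scores = model.decision_values(profiles)
    return EdgeScoreTable(
        [(model.tf, g, float(s)) for g, s in zip(candidate_genes, scores)]
    )


def infer_network(
    expression: ExpressionMatrix,
    known: RegulatoryNetwork,
    tfs: list[str],
    spec: KernelSpec,
    class_weight: str | None = None,
    score_norm: str = "none",
) -> EdgeScoreTable:
    """Train a local model per TF and pool decision values into one table.

    Pooling uses raw decision values by default; ``score_norm="rank"``
    rank-normalizes each local model's scores first.  TFs with no known
    targets cannot be trained; their candidate pairs get a -inf sentinel
    score (ranked last) so the output shape stays predictable, and the
    skipped TFs are logged.
    """
    entries: list[tuple[str, str, float]] = []
    n_trained = 0
    all_genes = sorted(known.genes)
    for tf in tfs:
        candidates = [g for g in all_genes if g != tf]
        labels = build_labels(known, tf)
        try:
            model = train_local_model(expression, labels, spec, class_weight)
        except UntrainableTFError as exc:
            logger.warning("skipping TF %s: %s", tf, exc)
            entries.extend((tf, g, SENTINEL_SCORE) for g in candidates)
            continue
        scored = score_genes(model, expression, candidates)
        values = _normalize_scores(np.array([s for _, _, s in scored.entries]), score_norm)
        entries.extend((tf, g, float(v)) for (tf, g, _), v in zip(scored.entries, values))
        n_trained += 1
    if n_trained == 0:
        raise UntrainableTFError(",".join(tfs), "no TF has any positive example")
    return EdgeScoreTable(entries)


def _tf_fold_seed(seed: int, tf: str) -> int:
    """Stable per-TF fold-shuffling seed (independent of hash randomization)."""
    return (int(seed) * 1000003 + zlib.crc32(tf.encode())) % (2**31 - 1)


def _cv_scores_one_tf(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    folds: int,
    random_state: int,
    class_weight=None,
) -> np.ndarray:
    """Held-out decision values for one TF's labeled genes.

    Folds are stratified on the positive/negative labels; the full Gram
    matrix is computed once and sliced per fold.
    """
    spec = spec.resolved(X.shape[1])
    K = gram_matrix(spec, X, X)
    scores = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        support, weights, bias, _ = _fit_dual(
            K[np.ix_(train_idx, train_idx)], y[train_idx], spec, class_weight
        )
        scores[test_idx] = weights @ K[np.ix_(train_idx[support], test_idx)] + bias
    return scores


def pooled_cv_scores(
    expression: ExpressionMatrix,
    known: RegulatoryNetwork,
    tfs: list[str],
    spec: KernelSpec,
    folds: int = 5,
    seed: int = 0,
    min_positives: int = 2,
    on_small: str = "sentinel",
    class_weight: str | None = None,
    score_norm: str = "none",
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Leak-free held-out scores for all (tf, gene) candidate pairs.

    Each TF's labeled genes are split into stratified folds (at most
    ``folds``, capped by the class counts); models trained on folds-1 score
    the held-out genes, and scores from all TFs and folds are pooled.

    TFs with fewer than ``min_positives`` positives (or negatives) cannot be
    cross-validated.  ``on_small='sentinel'`` keeps their pairs with a -inf
    score so the candidate universe is identical across methods;
    ``on_small='exclude'`` drops them from the pool (the grid-search
    objective).  Returns (pairs, scores, labels).
    """
    pairs: list[tuple[str, str]] = []
    scores: list[float] = []
    labels_01: list[int] = []
    for tf in tfs:
        lab = build_labels(known, tf)
        genes = sorted(lab.positives) + sorted(lab.negatives)
        y = np.array([1 if g in lab.positives else -1 for g in genes])
        n_pos, n_neg = len(lab.positives), len(lab.negatives)
        k = min(folds, n_pos, n_neg)
        if n_pos < min_positives or n_neg < min_positives or k < 2:
            if on_small == "exclude":
                logger.warning(
                    "TF %s excluded from CV scoring (%d positives, %d negatives)",
                    tf, n_pos, n_neg,
                )
                continue
            logger.warning(
                "TF %s has too few examples for CV (%d positives, %d negatives); "
                "its pairs get sentinel scores", tf, n_pos, n_neg,
            )
            pairs.extend((tf, g) for g in genes)
            scores.extend([SENTINEL_SCORE] * len(genes))
            labels_01.extend((y > 0).astype(int).tolist())
            continue
        std = standardize_profiles(expression)
        X = std.rows(genes)
        held_out = _normalize_scores(
            _cv_scores_one_tf(X, y, spec, k, _tf_fold_seed(seed, tf), class_weight),
            score_norm,
        )
        pairs.extend((tf, g) for g in genes)
        scores.extend(held_out.tolist())
        labels_01.extend((y > 0).astype(int).tolist())
    return pairs, np.asarray(scores), np.asarray(labels_01)


def grid_search(
    expression: ExpressionMatrix,
    known: RegulatoryNetwork,
    tfs: list[str],
    grid: list[KernelSpec],
    folds: int = 5,
    seed: int = 0,
    class_weight: str | None = None,
) -> GridSearchResult:
    """Pick the grid point with the best pooled cross-validated AUC.

    A grid point that overflows the kernel is recorded with AUC = NaN and
    skipped.  Ties are broken toward smaller C, then the smaller kernel
    parameter (gamma, alpha or degree), then declaration order.
    """
    from .evaluate import auc  # local import: evaluate also consumes this module

    if not grid:
        raise ValueError("grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cv_auc: dict[KernelSpec, float] = {}
    for spec in grid:
        try:
            _, scores, y01 = pooled_cv_scores(
                expression, known, tfs, spec, folds=folds, seed=seed,
                min_positives=folds, on_small="exclude", class_weight=class_weight,
            )
            if len(scores) == 0:
                raise UntrainableTFError(",".join(tfs), f"no TF has >= {folds} positives")
            cv_auc[spec] = auc(scores, y01)
        except KernelOverflowError as exc:
            logger.warning("grid point %s overflowed: %s", spec, exc)
            cv_auc[spec] = float("nan")
    finite = [(spec, a) for spec, a in cv_auc.items() if np.isfinite(a)]
    if not finite:
        raise KernelOverflowError("every grid point overflowed or failed")

    def _tiebreak(item):
        spec, a = item
        idx = grid.index(spec)
        return (-a, spec.C, spec.gamma or 0.0, spec.alpha, spec.d, idx)

    best_spec = min(finite, key=_tiebreak)[0]
    return GridSearchResult(best_spec=best_spec, cv_auc_by_point=cv_auc, folds=folds)
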