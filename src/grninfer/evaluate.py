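"""AUC scoring and the benchmark harness.

Prediction accuracy is the area under the ROC curve in its Mann-Whitney
form: the probability that a randomly chosen true edge outranks a randomly
chosen non-edge, with ties counted half.  Supervised methods are evaluated
leak-free — per-TF stratified cross-validation, held-out decision values
pooled over all TFs and folds — while the unsupervised CLR baseline scores
the same candidate-pair universe from expression alone.  The candidate
universe restricts TFs to genes with out-degree >= 1 in the gold standard
and excludes self-pairs.

``run_benchmark`` aggregates per-replicate AUCs into mean +/- sd per
(method, condition, network size), with "all" rows averaging across sizes
and across conditions, and keeps a per-replicate audit log so every
aggregate is recomputable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import (
    EdgeScoreTable,
    ExpressionMatrix,
    RegulatoryNetwork,
    write_ranked_edges,
)
from .kernels import KernelSpec
from .simulate import BenchmarkSuite

__all__ = [
    "Method",
    "BenchmarkResult",
    "auc",
    "evaluate_method",
    "run_benchmark",
    "predict",
    "default_methods",
]

logger = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with half-credit for ties.

    ``labels`` are 0/1; requires at least one positive and one negative.
    Computed from midranks: AUC = (R_pos - P(P+1)/2) / (P N), which equals
    the pair-counting definition (#{s_p > s_n} + 1/2 #{s_p == s_n}) / (P N)
    exactly, ties included.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if np.any(np.isnan(scores)):
        raise ValueError("scores must not contain NaN")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative label")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class Method:
    """A named inference method: a kernel SVM or a CLR variant.

    ``kind`` is ``"svm"`` (with a :class:`KernelSpec`) or ``"clr"`` (with an
    ``estimator`` of ``"pearson"`` or ``"spearman"``).
    """

    name: str
    kind: str
    spec: KernelSpec | None = None
    estimator: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "svm":
            if self.spec is None:
                raise ValueError(f"method {self.name!r}: svm methods need a KernelSpec")
        elif self.kind == "clr":
            if self.estimator not in ("pearson", "spearman"):
                raise ValueError(f"method {self.name!r}: clr estimator must be pearson or spearman")
        else:
            raise ValueError(f"method {self.name!r}: kind must be svm or clr")


def default_methods() -> list[Method]:
    """The standard comparison: four kernels plus two CLR estimators.

    Kernel hyperparameters are the package defaults: C = 1 everywhere,
    gaussian gamma = 1/n_features, polynomial (alpha=1, c=1, d=2), sigmoid
    (alpha=1, c=0), linear c = 0.
    """
    return [
        Method("svm-linear", "svm", spec=KernelSpec("linear", c=0.0, C=1.0)),
        Method("svm-polynomial", "svm", spec=KernelSpec("polynomial", alpha=1.0, c=1.0, d=2, C=1.0)),
        Method("svm-gaussian", "svm", spec=KernelSpec("gaussian", gamma=None, C=1.0)),
        Method("svm-sigmoid", "svm", spec=KernelSpec("sigmoid", alpha=1.0, c=0.0, C=1.0)),
        Method("clr-pearson", "clr", estimator="pearson"),
        Method("clr-spearman", "clr", estimator="spearman"),
    ]


def candidate_universe(network: RegulatoryNetwork) -> tuple[list[tuple[str, str]], np.ndarray]:
    """All (tf, gene) pairs with tf out-degree >= 1 and gene != tf, plus 0/1 labels."""
    tfs = network.tfs()
    if not tfs:
        raise ValueError("network has no TF (no gene with out-degree >= 1)")
    genes = sorted(network.genes)
    pairs = [(tf, g) for tf in tfs for g in genes if g != tf]
    edge_pairs = network.edge_pairs
    labels = np.array([1 if p in edge_pairs else 0 for p in pairs])
    return pairs, labels


def evaluate_method(
    method: Method,
    replicate: tuple[RegulatoryNetwork, ExpressionMatrix],
    folds: int = 5,
    seed: int = 0,
) -> float:
    """One replicate's AUC for one method over the shared candidate universe.

    Supervised: per-TF stratified cross-validation (fold count capped by the
    class counts), held-out decision values pooled across TFs and folds;
    TFs too small to cross-validate keep their pairs with a -inf sentinel so
    both method families see the identical label vector.  Unsupervised:
    CLR scores from expression alone on the same pairs.
    """
    from . import clr as clr_mod
    from . import supervised

    network, expression = replicate
    pairs, labels = candidate_universe(network)
    if method.kind == "clr":
        mi = clr_mod.mi_matrix(expression, method.estimator)
        table = clr_mod.clr_edge_table(clr_mod.clr_scores(mi), network.tfs())
        lookup = table.as_dict()
        scores = np.array([lookup[p] for p in pairs])
    else:
        cv_pairs, cv_scores, _ = supervised.pooled_cv_scores(
            expression, network, network.tfs(), method.spec,
            folds=folds, seed=seed, min_positives=2, on_small="sentinel",
        )
        lookup = dict(zip(cv_pairs, cv_scores))
        scores = np.array([lookup[p] for p in pairs])
    return auc(scores, labels)


@dataclass
class BenchmarkResult:
    """Aggregate AUC table plus the per-replicate audit log.

    ``table`` columns: method, condition, size, mean_auc, sd_auc,
    n_replicates.  Rows with size "all" average replicate AUCs across sizes
    of one condition; the (condition="all", size="all") row averages across
    everything.  ``per_replicate`` columns: method, condition, size,
    replicate, auc.
    """

    table: pd.DataFrame
    per_replicate: pd.DataFrame

    def lookup(self, method: str, condition: str, size) -> pd.Series:
        t = self.table
        hit = t[(t.method == method) & (t.condition == condition) & (t["size"].astype(str) == str(size))]
        if hit.empty:
            raise KeyError(f"no benchmark row ({method}, {condition}, {size})")
        return hit.iloc[0]


def _aggregate(aucs: list[float]) -> tuple[float, float, int]:
    arr = np.asarray(aucs, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return mean, sd, len(arr)


def run_benchmark(
    suites: list[BenchmarkSuite],
    methods: list[Method],
    folds: int = 5,
    seed: int = 0,
) -> BenchmarkResult:
    """Evaluate every method on every replicate of every suite.

    A replicate that raises is recorded as missing and excluded from its
    cell's mean/sd, with a logged count.  Deterministic given ``seed``.
    """
    if not suites:
        raise ValueError("need at least one benchmark suite")
    names = [m.name for m in methods]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate method names in {names}")
    records = []
    n_failed = 0
    for suite in suites:
        for rep_idx, replicate in enumerate(suite.replicates):
            for method in methods:
                try:
                    value = evaluate_method(
                        method, replicate, folds=folds,
                        seed=(seed * 7919 + rep_idx) % (2**31 - 1),
                    )
                except Exception as exc:  # failed replicate: record as missing
                    n_failed += 1
                    logger.warning(
                        "replicate %s/%s/rep%d failed for %s: %s",
                        suite.condition, suite.size, rep_idx, method.name, exc,
                    )
                    continue
                records.append(
                    {
                        "method": method.name,
                        "condition": suite.condition,
                        "size": suite.size,
                        "replicate": rep_idx,
                        "auc": value,
                    }
                )
    if n_failed:
        logger.warning("%d replicate evaluations failed and were excluded", n_failed)
    per_replicate = pd.DataFrame.from_records(
        records, columns=["method", "condition", "size", "replicate", "auc"]
    )
    rows = []
    for (method, condition, size), group in per_replicate.groupby(
        ["method", "condition", "size"], sort=True
    ):
        mean, sd, n = _aggregate(group["auc"].tolist())
        rows.append((method, condition, size, mean, sd, n))
    for (method, condition), group in per_replicate.groupby(["method", "condition"], sort=True):
        mean, sd, n = _aggregate(group["auc"].tolist())
        rows.append((method, condition, "all", mean, sd, n))
    for method, group in per_replicate.groupby("method", sort=True):
        mean, sd, n = _aggregate(group["auc"].tolist())
        rows.append((method, "all", "all", mean, sd, n))
    table = pd.DataFrame(
        rows, columns=["method", "condition", "size", "mean_auc", "sd_auc", "n_replicates"]
    )
    return BenchmarkResult(table=table, per_replicate=per_replicate)


def predict(
    expression: ExpressionMatrix,
    known: RegulatoryNetwork,
    spec: KernelSpec,
    out=None,
) -> EdgeScoreTable:
    """Train on all known regulations and rank novel candidate edges.

    Every (tf, gene) pair already present in the gold standard is excluded
    from the output; the remaining pairs are ranked by decision value and
    optionally written as a ranked TSV.
    """
    from . import supervised

    full = supervised.infer_network(expression, known, known.tfs(), spec)
    known_pairs = known.edge_pairs
    novel = EdgeScoreTable(
        [e for e in full.entries if (e[0], e[1]) not in known_pairs]
    )
    if out is not None:
        write_ranked_edges(novel, out)
    return novel
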