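"""Local per-TF classifiers, score pooling and grid search."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from grninfer import (
    ExpressionMatrix,
    KernelSpec,
    LabelSet,
    RegulatoryNetwork,
    UntrainableTFError,
    auc,
    build_labels,
    grid_search,
    gram_matrix,
    infer_network,
    score_genes,
    standardize_profiles,
    train_local_model,
)
from grninfer.supervised import _tf_fold_seed, pooled_cv_scores


def separable_toy(rng, n_per_class=10, n_features=6, gap=8.0):
    """Two well-separated Gaussian clusters of gene profiles for one TF.

    Positives cluster around +gap in half the coordinates, negatives around
    -gap, with unit noise, so the margin dwarfs the noise.
    """
    center = np.zeros(n_features)
    center[: n_features // 2] = gap
    pos = center + rng.normal(size=(n_per_class, n_features))
    neg = -center + rng.normal(size=(n_per_class, n_features))
    genes = ["tf"] + [f"p{i}" for i in range(n_per_class)] + [f"n{i}" for i in range(n_per_class)]
    values = np.vstack([rng.normal(size=n_features), pos, neg])
    expr = ExpressionMatrix(genes, [f"e{j}" for j in range(n_features)], values)
    net = RegulatoryNetwork(set(genes), {("tf", f"p{i}"): 1 for i in range(n_per_class)})
    return net, expr


class TestTrainLocalModel:
    def test_two_point_problem_orders_scores(self):
        expr = ExpressionMatrix(
            ["tf", "pos", "neg"], ["e1", "e2"], [[0.0, 0.1], [1.0, 1.2], [-1.0, -1.1]]
        )
        labels = LabelSet("tf", {"pos"}, {"neg"})
        model = train_local_model(expr, labels, KernelSpec("linear", C=1.0))
        table = score_genes(model, expr, ["pos", "neg"]).as_dict()
        assert table[("tf", "pos")] > table[("tf", "neg")]

    def test_empty_positive_set_is_untrainable(self, small_expression):
        labels = LabelSet("g0", set(), {"g1", "g2"})
        with pytest.raises(UntrainableTFError, match="g0"):
            train_local_model(small_expression, labels, KernelSpec("gaussian"))

    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        net, expr = separable_toy(rng)
        labels = build_labels(net, "tf")
        model = train_local_model(expr, labels, KernelSpec("gaussian", C=1.0))
        scores = score_genes(model, expr, sorted(labels.positives | labels.negatives)).as_dict()
        assert all(scores[("tf", g)] > 0 for g in labels.positives)
        assert all(scores[("tf", g)] < 0 for g in labels.negatives)

    def test_dual_weights_satisfy_soft_margin_constraints(self, rng):
        net, expr = separable_toy(rng)
        model = train_local_model(expr, build_labels(net, "tf"), KernelSpec("gaussian", C=0.5))
        assert abs(model.weights.sum()) < 1e-6
        assert np.all(np.abs(model.weights) <= 0.5 + 1e-9)


class TestScoreGenes:
    def test_one_entry_per_candidate(self, rng):
        net, expr = separable_toy(rng)
        model = train_local_model(expr, build_labels(net, "tf"), KernelSpec("linear"))
        table = score_genes(model, expr, ["p0", "p1", "n0"])
        assert len(table) == 3

    def test_identical_profiles_get_identical_scores(self, rng):
        net, expr = separable_toy(rng)
        dup = ExpressionMatrix(
            list(expr.gene_ids) + ["clone"],
            expr.experiment_ids,
            np.vstack([expr.values, expr.row("p0")]),
        )
        net2 = RegulatoryNetwork(net.genes | {"clone"}, net.edges)
        model = train_local_model(dup, build_labels(net2, "tf"), KernelSpec("gaussian"))
        scores = score_genes(model, dup, ["p0", "clone"]).as_dict()
        assert scores[("tf", "p0")] == pytest.approx(scores[("tf", "clone")], abs=1e-12)

    def test_tf_cannot_be_its_own_candidate(self, rng):
        net, expr = separable_toy(rng)
        model = train_local_model(expr, build_labels(net, "tf"), KernelSpec("linear"))
        with pytest.raises(ValueError, match="own candidate"):
            score_genes(model, expr, ["tf", "p0"])


class TestDecisionFunctionReconstruction:
    @pytest.mark.parametrize("spec", [
        KernelSpec("linear", c=0.0, C=2.0),
        KernelSpec("polynomial", alpha=0.1, c=1.0, d=3, C=1.0),
        KernelSpec("gaussian", gamma=0.05, C=1.0),
        KernelSpec("sigmoid", alpha=0.2, c=0.0, C=1.0),
    ])
    def test_stored_dual_form_reproduces_the_trainer(self, spec, rng):
        # independent route: a fresh libsvm fit scored via decision_function
        genes = [f"g{i}" for i in range(30)]
        expr = ExpressionMatrix(genes, [f"e{j}" for j in range(15)], rng.normal(size=(30, 15)))
        net = RegulatoryNetwork(set(genes), {("g0", f"g{i}"): 1 for i in range(1, 9)})
        labels = build_labels(net, "g0")
        model = train_local_model(expr, labels, spec)

        order = sorted(labels.positives) + sorted(labels.negatives)
        X = standardize_profiles(expr).rows(order)
        y = np.array([1 if g in labels.positives else -1 for g in order])
        svc = SVC(C=spec.C, kernel="precomputed").fit(gram_matrix(model.spec, X, X), y)
        queries = rng.normal(size=(100, 15))
        native = svc.decision_function(gram_matrix(model.spec, queries, X))
        np.testing.assert_allclose(model.decision_values(queries), native, atol=1e-6)


class TestInferNetwork:
    def test_candidate_table_shape(self, rng):
        genes = [f"g{i}" for i in range(10)]
        expr = ExpressionMatrix(genes, [f"e{j}" for j in range(6)], rng.normal(size=(10, 6)))
        net = RegulatoryNetwork(
            set(genes), {("g0", "g2"): 1, ("g0", "g3"): 1, ("g1", "g4"): 1, ("g1", "g5"): 1}
        )
        table = infer_network(expr, net, ["g0", "g1"], KernelSpec("linear"))
        assert len(table) == 2 * 9

    def test_gene_order_does_not_change_scores(self, rng):
        genes = [f"g{i}" for i in range(8)]
        values = rng.normal(size=(8, 5))
        expr = ExpressionMatrix(genes, [f"e{j}" for j in range(5)], values)
        perm = rng.permutation(8)
        shuffled = ExpressionMatrix([genes[i] for i in perm], expr.experiment_ids, values[perm])
        net = RegulatoryNetwork(set(genes), {("g0", "g2"): 1, ("g0", "g5"): 1})
        t1 = infer_network(expr, net, ["g0"], KernelSpec("gaussian")).as_dict()
        t2 = infer_network(shuffled, net, ["g0"], KernelSpec("gaussian")).as_dict()
        for pair, score in t1.items():
            assert score == pytest.approx(t2[pair], abs=1e-12)

    def test_targetless_tf_gets_sentinel_scores(self, rng):
        genes = [f"g{i}" for i in range(6)]
        expr = ExpressionMatrix(genes, [f"e{j}" for j in range(4)], rng.normal(size=(6, 4)))
        net = RegulatoryNetwork(set(genes), {("g0", "g1"): 1})
        table = infer_network(expr, net, ["g0", "g2"], KernelSpec("linear")).as_dict()
        assert all(table[("g2", g)] == float("-inf") for g in genes if g != "g2")
        assert np.isfinite(table[("g0", "g1")])

    def test_no_trainable_tf_raises(self, rng):
        genes = [f"g{i}" for i in range(4)]
        expr = ExpressionMatrix(genes, [f"e{j}" for j in range(4)], rng.normal(size=(4, 4)))
        net = RegulatoryNetwork(set(genes), {("g0", "g1"): 1})
        with pytest.raises(UntrainableTFError):
            infer_network(expr, net, ["g2"], KernelSpec("linear"))

    def test_rank_normalized_pooling_preserves_within_tf_order(self, rng):
        genes = [f"g{i}" for i in range(10)]
        expr = ExpressionMatrix(genes, [f"e{j}" for j in range(6)], rng.normal(size=(10, 6)))
        net = RegulatoryNetwork(
            set(genes), {("g0", "g2"): 1, ("g0", "g3"): 1, ("g1", "g4"): 1, ("g1", "g5"): 1}
        )
        raw = infer_network(expr, net, ["g0", "g1"], KernelSpec("linear")).as_dict()
        ranked = infer_network(
            expr, net, ["g0", "g1"], KernelSpec("linear"), score_norm="rank"
        ).as_dict()
        assert all(0.0 < v <= 1.0 for v in ranked.values())
        for tf in ("g0", "g1"):
            others = [g for g in genes if g != tf]
            raw_order = sorted(others, key=lambda g: raw[(tf, g)])
            rank_order = sorted(others, key=lambda g: ranked[(tf, g)])
            assert raw_order == rank_order

    def test_determinism(self, rng):
        net, expr = separable_toy(rng)
        spec = KernelSpec("gaussian", C=1.0)
        t1 = infer_network(expr, net, ["tf"], spec)
        t2 = infer_network(expr, net, ["tf"], spec)
        assert t1.entries == t2.entries


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self, rng):
        net, expr = separable_toy(rng)
        spec = KernelSpec("gaussian", C=1.0)
        result = grid_search(expr, net, ["tf"], [spec], folds=5, seed=3)
        assert result.best_spec == spec
        assert result.folds == 5

    def test_tiny_c_underfits_and_loses(self, rng):
        # one modest separating dimension drowned in high-variance nuisance
        # dimensions: a vanishing C reduces the classifier to a class-mean
        # difference, which the nuisance noise swamps; C = 1 fits the margin
        n, p = 14, 40
        pos = np.hstack([rng.normal(1.0, 0.1, size=(n, 1)), rng.normal(0, 3.0, size=(n, p - 1))])
        neg = np.hstack([rng.normal(-1.0, 0.1, size=(n, 1)), rng.normal(0, 3.0, size=(n, p - 1))])
        genes = ["tf"] + [f"p{i}" for i in range(n)] + [f"n{i}" for i in range(n)]
        expr = ExpressionMatrix(
            genes, [f"e{j}" for j in range(p)], np.vstack([rng.normal(size=p), pos, neg])
        )
        net = RegulatoryNetwork(set(genes), {("tf", f"p{i}"): 1 for i in range(n)})
        good, tiny = KernelSpec("linear", C=1.0), KernelSpec("linear", C=1e-6)
        result = grid_search(expr, net, ["tf"], [good, tiny], folds=5, seed=3)
        assert result.best_spec == good
        assert result.cv_auc_by_point[tiny] < result.cv_auc_by_point[good] - 0.1
        assert 0.35 <= result.cv_auc_by_point[tiny] <= 0.65

    def test_matches_independent_fold_loop(self, rng):
        # brute-force re-evaluation: same folds, independent SVC fits
        net, expr = separable_toy(rng, n_per_class=8)
        grid = [KernelSpec("gaussian", gamma=g, C=1.0) for g in (0.01, 0.1)]
        folds, seed = 4, 9
        result = grid_search(expr, net, ["tf"], grid, folds=folds, seed=seed)

        labels = build_labels(net, "tf")
        order = sorted(labels.positives) + sorted(labels.negatives)
        X = standardize_profiles(expr).rows(order)
        y = np.array([1 if g in labels.positives else -1 for g in order])
        for spec in grid:
            K = gram_matrix(spec, X, X)
            held = np.empty(len(y))
            skf = StratifiedKFold(folds, shuffle=True, random_state=_tf_fold_seed(seed, "tf"))
            for tr, te in skf.split(np.zeros(len(y)), y):
                svc = SVC(C=spec.C, kernel="precomputed").fit(K[np.ix_(tr, tr)], y[tr])
                held[te] = svc.decision_function(K[np.ix_(te, tr)])
            expected = auc(held, (y > 0).astype(int))
            assert result.cv_auc_by_point[spec] == pytest.approx(expected, abs=1e-12)

    def test_all_overflowing_grid_raises(self, rng):
        net, expr = separable_toy(rng)
        bad = KernelSpec("polynomial", alpha=1e200, c=0.0, d=4)
        with pytest.raises(Exception, match="overflow"):
            grid_search(expr, net, ["tf"], [bad], folds=3, seed=1)


class TestPooledCVScores:
    def test_label_permutation_gives_chance_level_auc(self, rng):
        # no leakage: permuted labels must not be learnable
        net, expr = separable_toy(rng, n_per_class=10)
        genes = sorted(net.genes - {"tf"})
        aucs = []
        for k in range(10):
            perm = np.random.default_rng(k).choice(genes, size=10, replace=False)
            pnet = RegulatoryNetwork(net.genes, {("tf", str(g)): 1 for g in perm})
            _, scores, labels = pooled_cv_scores(
                expr, pnet, ["tf"], KernelSpec("gaussian", C=1.0), folds=5, seed=k
            )
            aucs.append(auc(scores, labels))
        assert 0.35 <= np.mean(aucs) <= 0.65
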