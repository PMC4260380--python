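import numpy as np
import pytest

from grninfer import ExpressionMatrix, RegulatoryNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20240395)


@pytest.fixture
def small_expression(rng):
    """12 genes x 8 experiments of i.i.d. normal expression."""
    genes = [f"g{i}" for i in range(12)]
    exps = [f"e{j}" for j in range(8)]
    return ExpressionMatrix(genes, exps, rng.normal(size=(12, 8)))


@pytest.fixture
def small_network():
    genes = {f"g{i}" for i in range(12)}
    edges = {
        ("g0", "g2"): +1,
        ("g0", "g3"): +1,
        ("g0", "g4"): -1,
        ("g1", "g5"): +1,
        ("g1", "g6"): +1,
    }
    return RegulatoryNetwork(genes, edges)


def random_network(n_genes: int, n_tfs: int, rng) -> RegulatoryNetwork:
    """Random directed network helper for property checks."""
    genes = [f"g{i}" for i in range(n_genes)]
    edges = {}
    for gene in genes:
        for tf in rng.choice(genes[:n_tfs], size=rng.integers(0, n_tfs), replace=False):
            if tf != gene:
                edges[(str(tf), gene)] = +1 if rng.random() < 0.7 else -1
    return RegulatoryNetwork(set(genes), edges)
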