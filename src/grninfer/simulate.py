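"""Steady-state perturbation benchmark generator.

Emulates the in-silico benchmark workflow used for network-inference
evaluation: a subnetwork is extracted from a larger source regulatory
network, gene expression dynamics are modelled with Hill-kinetics
transcription and first-order decay,

    dx_i/dt = m_i * [b_i + (V_i - b_i) * prod_r e_r(x_r)] - lambda_i * x_i

with e_r = x_r^h / (x_r^h + K^h) for activators and 1 - e_r for repressors,
and steady states are measured under three experiment designs:

* knockout      — one experiment per gene; the gene's transcription-rate
                  multiplier m is clamped to 0 and its measured value is
                  forced to exactly zero;
* knockdown     — one experiment per gene with m clamped to 0.5 (halved);
* multifactorial — as many experiments as genes, each perturbing a small
                  random subset of genes (10%) by small random multipliers
                  drawn from U[0.75, 1.25].

Every measurement is multiplied by log-normal noise.  In all designs the
experiment count equals the gene count.  Steady states are found by damped
fixed-point iteration rather than stiff ODE integration — only fixed
points are needed, and non-convergence is an explicit error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .data import (
    ExpressionMatrix,
    RegulatoryNetwork,
    read_expression,
    read_gold_standard,
    write_expression,
    write_gold_standard,
)

__all__ = [
    "CONDITIONS",
    "KineticsParams",
    "BenchmarkSuite",
    "ConvergenceError",
    "random_source_network",
    "extract_subnetwork",
    "steady_state",
    "generate_condition",
    "generate_benchmark",
    "indicator_instance",
    "write_suite",
    "read_suite",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("knockout", "knockdown", "multifactorial")

# Fraction of genes perturbed per multifactorial experiment and the
# multiplier range of the "small random" perturbation.
MULTIFACTORIAL_FRACTION = 0.1
MULTIFACTORIAL_RANGE = (0.75, 1.25)


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach a steady state."""


@dataclass(frozen=True)
class KineticsParams:
    """Hill-kinetics rates shared by the simulator.

    ``basal`` and ``vmax`` are per-gene arrays (basal and maximal
    transcription rates, vmax >= basal); ``hill_k``/``hill_n`` are the
    shared half-saturation constant and Hill coefficient; ``decay`` is the
    per-gene first-order degradation rate; ``noise_sd`` is the sd of the
    multiplicative log-normal measurement noise.
    """

    basal: np.ndarray
    vmax: np.ndarray
    hill_k: float = 1.0
    hill_n: float = 2.0
    decay: np.ndarray = None
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "basal", np.asarray(self.basal, dtype=float))
        object.__setattr__(self, "vmax", np.asarray(self.vmax, dtype=float))
        decay = np.ones_like(self.basal) if self.decay is None else np.asarray(self.decay, dtype=float)
        object.__setattr__(self, "decay", decay)
        if np.any(self.basal <= 0) or np.any(self.decay <= 0):
            raise ValueError("basal and decay rates must be positive")
        if np.any(self.vmax < self.basal):
            raise ValueError("vmax must be >= basal for every gene")
        if not self.hill_k > 0 or self.hill_n < 1:
            raise ValueError("need hill_k > 0 and hill_n >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def random(cls, n_genes: int, rng: np.random.Generator, noise_sd: float = 0.05) -> "KineticsParams":
        """Default per-gene rates: b ~ U[0.5, 1.5], V = 5 b, lambda = 1."""
        basal = rng.uniform(0.5, 1.5, size=n_genes)
        return cls(basal=basal, vmax=5.0 * basal, decay=np.ones(n_genes), noise_sd=noise_sd)


@dataclass
class BenchmarkSuite:
    """Replicate (network, expression) pairs for one (condition, size) cell."""

    condition: str
    size: int
    replicates: list[tuple[RegulatoryNetwork, ExpressionMatrix]]
    seed: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for network, expression in self.replicates:
            if set(expression.gene_ids) != network.genes:
                raise ValueError("replicate expression must cover exactly its network's genes")
            if expression.n_experiments != len(network.genes):
                raise ValueError("experiment count must equal gene count")


def random_source_network(
    n_genes: int,
    n_tfs: int,
    edges_per_gene: float = 2.0,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Scale-free-ish directed source network emulating a bacterial GRN.

    Every gene draws max(1, Poisson(edges_per_gene)) regulators from the TF
    subset by preferential attachment on current TF out-degree (producing
    hub regulators with large regulons, as in E. coli); edge signs are +1
    (activation) with probability 0.7, -1 with probability 0.3.  Because
    every gene has at least one TF regulator (except a lone root TF), the
    network is weakly connected.  The default density of ~2 edges per gene
    matches E. coli-derived benchmark subnetworks.
    """
    if not 1 <= n_tfs <= n_genes:
        raise ValueError("need 1 <= n_tfs <= n_genes")
    if edges_per_gene <= 0:
        raise ValueError("edges_per_gene must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    tfs = genes[:n_tfs]
    out_degree = {tf: 0 for tf in tfs}
    edges: dict[tuple[str, str], int] = {}
    for gene in genes:
        pool = [tf for tf in tfs if tf != gene]
        if not pool:
            continue
        k = min(max(1, rng.poisson(edges_per_gene)), len(pool))
        chosen: list[str] = []
        for _ in range(k):
            remaining = [tf for tf in pool if tf not in chosen]
            weights = np.array([out_degree[tf] + 1.0 for tf in remaining])
            tf = remaining[rng.choice(len(remaining), p=weights / weights.sum())]
            chosen.append(tf)
            out_degree[tf] += 1
            sign = +1 if rng.random() < 0.7 else -1
            edges[(tf, gene)] = sign
    return RegulatoryNetwork(set(genes), edges)


def extract_subnetwork(source: RegulatoryNetwork, n: int, seed: int = 0) -> RegulatoryNetwork:
    """Grow a random weakly connected vertex set of size ``n``; induce it.

    Starting from a random seed vertex, the set is repeatedly extended by a
    uniformly random undirected neighbor of the current set.
    """
    if n < 1 or n > len(source.genes):
        raise ValueError(f"subnetwork size {n} out of range 1..{len(source.genes)}")
    rng = np.random.default_rng(seed)
    graph = source.to_networkx()
    undirected = graph.to_undirected()
    nodes = sorted(source.genes)
    selected = {nodes[rng.integers(len(nodes))]}
    while len(selected) < n:
        frontier = sorted(
            {nb for v in selected for nb in undirected.neighbors(v)} - selected
        )
        if not frontier:
            raise ValueError(
                f"neighborhood growth exhausted at {len(selected)} < {n} vertices; "
                "try another seed"
            )
        selected.add(frontier[rng.integers(len(frontier))])
    induced = graph.subgraph(selected).copy()
    return RegulatoryNetwork.from_networkx(induced)


def steady_state(
    network: RegulatoryNetwork,
    params: KineticsParams,
    clamp: dict[str, float] | None = None,
    eta: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Steady-state expression vector (gene order = sorted network genes).

    ``clamp`` maps gene ids to transcription-rate multipliers m >= 0
    (0 = knockout, 0.5 = knockdown, 1 = wild type).  Solved by damped
    fixed-point iteration x <- (1 - eta) x + eta * production / decay from
    the regulator-free state x = b / lambda.
    """
    genes = sorted(network.genes)
    n = len(genes)
    if len(params.basal) != n:
        raise ValueError(f"params sized for {len(params.basal)} genes, network has {n}")
    clamp = clamp or {}
    if any(m < 0 for m in clamp.values()):
        raise ValueError("clamp multipliers must be >= 0")
    index = {g: i for i, g in enumerate(genes)}
    m = np.ones(n)
    for g, mult in clamp.items():
        m[index[g]] = mult
    regulators = [network.regulators_of(g) for g in genes]
    reg_idx = [np.array([index[r] for r, _ in regs], dtype=int) for regs in regulators]
    reg_sign = [np.array([s for _, s in regs]) for regs in regulators]

    b, V, lam = params.basal, params.vmax, params.decay
    K_h = params.hill_k ** params.hill_n
    x = b / lam
    for iteration in range(max_iter):
        xh = np.maximum(x, 0.0) ** params.hill_n
        act = xh / (xh + K_h)
        production = b.copy()
        for i in range(n):
            if reg_idx[i].size:
                e = np.where(reg_sign[i] > 0, act[reg_idx[i]], 1.0 - act[reg_idx[i]])
                production[i] = b[i] + (V[i] - b[i]) * e.prod()
        x_new = (1.0 - eta) * x + eta * m * production / lam
        delta = np.abs(x_new - x).max()
        x = x_new
        if delta < tol:
            return np.maximum(x, 0.0)
    raise ConvergenceError(
        f"no steady state after {max_iter} iterations (last max |dx| = {delta:.3e})"
    )


def generate_condition(
    network: RegulatoryNetwork,
    params: KineticsParams,
    condition: str,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate one experiment design for one network.

    Produces an n-gene x n-experiment matrix: per-gene knockout or
    knockdown columns, or n multifactorial perturbation columns.  All
    measurements carry multiplicative log-normal noise; knocked-out genes
    are measured as exactly zero.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    genes = sorted(network.genes)
    n = len(genes)
    rng = np.random.default_rng(seed)
    columns: list[np.ndarray] = []
    labels: list[str] = []
    if condition in ("knockout", "knockdown"):
        mult = 0.0 if condition == "knockout" else 0.5
        prefix = "ko" if condition == "knockout" else "kd"
        for g in genes:
            columns.append(steady_state(network, params, {g: mult}))
            labels.append(f"{prefix}_{g}")
    else:
        n_perturbed = int(np.ceil(MULTIFACTORIAL_FRACTION * n))
        lo, hi = MULTIFACTORIAL_RANGE
        for k in range(n):
            chosen = rng.choice(n, size=n_perturbed, replace=False)
            clamp = {genes[i]: rng.uniform(lo, hi) for i in sorted(chosen)}
            columns.append(steady_state(network, params, clamp))
            labels.append(f"mf_{k:03d}")
    values = np.column_stack(columns)
    if params.noise_sd > 0:
        values = values * rng.lognormal(0.0, params.noise_sd, size=values.shape)
    if condition == "knockout":
        for j, g in enumerate(genes):
            values[j, j] = 0.0  # the knocked-out gene is measured as zero
    return ExpressionMatrix(genes, labels, values)


def _replicate_seed(seed: int, condition: str, size: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        entropy=int(seed) % (2**31),
        spawn_key=(CONDITIONS.index(condition), int(size), int(rep)),
    )


def generate_benchmark(
    sizes: list[int],
    conditions: list[str],
    replicates: int = 10,
    seed: int = 0,
    source: RegulatoryNetwork | None = None,
    noise_sd: float = 0.05,
) -> list[BenchmarkSuite]:
    """Generate ``replicates`` (subnetwork, expression) pairs per cell.

    The source network defaults to a random scale-free-ish network with
    2 * max(sizes) genes, a 5% TF fraction and ~2 edges per gene (E. coli-
    like regulon statistics: few hub TFs with large regulons).  Per-replicate
    seeds are derived deterministically from ``seed``, the condition and the
    size, so identical calls yield bit-identical suites.
    """
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("sizes must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for condition in conditions:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
    if source is None:
        n_source = 2 * max(sizes)
        source = random_source_network(
            n_source,
            n_tfs=max(2, round(0.05 * n_source)),
            edges_per_gene=2.0,
            seed=np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(99,)).generate_state(1)[0] % (2**31),
        )
    suites = []
    for condition in conditions:
        for size in sizes:
            pairs = []
            for rep in range(replicates):
                ss = _replicate_seed(seed, condition, size, rep)
                extract_seed, params_seed, sim_seed = [
                    int(s) % (2**31) for s in ss.generate_state(3)
                ]
                network = extract_subnetwork(source, size, seed=extract_seed)
                params = KineticsParams.random(
                    size, np.random.default_rng(params_seed), noise_sd=noise_sd
                )
                expression = generate_condition(network, params, condition, seed=sim_seed)
                pairs.append((network, expression))
            suites.append(BenchmarkSuite(condition, size, pairs, seed))
    return suites


def indicator_instance(
    n_genes: int = 20,
    n_tfs: int = 3,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[RegulatoryNetwork, ExpressionMatrix]:
    """Perfectly informative synthetic instance for sanity checks.

    Each gene's expression profile is the 0/1 indicator of which TFs
    regulate it (one experiment per TF, plus an equal number of baseline
    experiments where nothing is induced) plus Gaussian noise, so genes
    sharing a regulator are trivially separable from the rest.  The
    baseline columns keep distinct indicator patterns distinct after
    per-gene standardization (without them, patterns that are affine
    transforms of one another — e.g. all-ones vs. all-zeros — collapse).
    A sound supervised method must recover the network near-perfectly
    here; with permuted labels it must fall back to chance.
    """
    if n_tfs < 1 or n_genes <= n_tfs:
        raise ValueError("need at least one TF and more genes than TFs")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    tfs = genes[:n_tfs]
    edges: dict[tuple[str, str], int] = {}
    for gene in genes[n_tfs:]:
        k = 1 + rng.integers(n_tfs)  # 1..n_tfs regulators
        for tf in rng.choice(tfs, size=k, replace=False):
            edges[(str(tf), gene)] = +1
    network = RegulatoryNetwork(set(genes), edges)
    profiles = np.zeros((n_genes, 2 * n_tfs))
    for (tf, target) in network.edges:
        profiles[genes.index(target), tfs.index(tf)] = 1.0
    profiles += rng.normal(0.0, noise_sd, size=profiles.shape)
    labels = [f"exp_{tf}" for tf in tfs] + [f"baseline_{k}" for k in range(n_tfs)]
    expression = ExpressionMatrix(genes, labels, profiles)
    return network, expression


def write_suite(suite: BenchmarkSuite, out_dir) -> None:
    """Write replicates under <out_dir>/<condition>/<size>/rep<k>/ with a manifest."""
    base = Path(out_dir) / suite.condition / str(suite.size)
    for k, (network, expression) in enumerate(suite.replicates):
        rep_dir = base / f"rep{k}"
        rep_dir.mkdir(parents=True, exist_ok=True)
        write_expression(expression, rep_dir / "expression.tsv")
        write_gold_standard(network, rep_dir / "goldstandard.tsv")
    manifest = {
        "condition": suite.condition,
        "size": suite.size,
        "replicates": len(suite.replicates),
        "seed": suite.seed,
    }
    with open(base / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def read_suite(condition_size_dir) -> BenchmarkSuite:
    """Read a suite previously written by :func:`write_suite`."""
    base = Path(condition_size_dir)
    with open(base / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    pairs = []
    for k in range(int(manifest["replicates"])):
        rep_dir = base / f"rep{k}"
        expression = read_expression(rep_dir / "expression.tsv")
        network = read_gold_standard(rep_dir / "goldstandard.tsv", set(expression.gene_ids))
        pairs.append((network, expression))
    return BenchmarkSuite(manifest["condition"], int(manifest["size"]), pairs, int(manifest["seed"]))
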