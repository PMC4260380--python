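"""Core domain types and plain-text I/O.

Expression compendia are tab-separated matrices with genes as rows and
experiments as columns; regulatory networks are directed TF -> target edge
sets read from the three-column ``goldstandard`` dialect (tf, target, 0/1);
ranked predictions are written as tab-separated (tf, gene, score) triples
sorted by decreasing score.

Supervised training labels follow the closed-world convention: for a given
transcription factor, every known target is a positive and every other gene
(except the TF itself) is a negative.  Negative regulations are rarely
curated, so absence of evidence is treated as a negative example.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "RegulatoryNetwork",
    "LabelSet",
    "EdgeScoreTable",
    "read_expression",
    "write_expression",
    "read_gold_standard",
    "write_gold_standard",
    "build_labels",
    "write_ranked_edges",
    "read_ranked_edges",
]


class FormatError(ValueError):
    """Malformed input file or invariant violation in a domain object."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-experiment real matrix with row/column identifiers.

    Rows are genes, columns are experiments, so each row is one gene's
    expression profile across the compendium — the feature vector used by
    the kernel classifiers.
    """

    gene_ids: list[str]
    experiment_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.experiment_ids = [str(e).strip() for e in self.experiment_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.experiment_ids)):
            raise FormatError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.experiment_ids)} experiments"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise FormatError(f"duplicate gene id {dup!r}")
        dup = _first_duplicate(self.experiment_ids)
        if dup is not None:
            raise FormatError(f"duplicate experiment id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value for gene {self.gene_ids[i]!r}, "
                f"experiment {self.experiment_ids[j]!r}"
            )
        self._row_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def row(self, gene: str) -> np.ndarray:
        """Expression profile of ``gene`` (view into the matrix)."""
        try:
            return self.values[self._row_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def rows(self, genes: list[str]) -> np.ndarray:
        return self.values[[self._row_index[g] for g in genes]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._row_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.experiment_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


def read_expression(path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First row: experiment labels; first column: gene ids.  Raises
    :class:`FormatError` naming the offending gene/experiment for duplicate
    identifiers, non-numeric cells and ragged rows.
    """
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        experiment_ids = [tok.strip() for tok in header.rstrip("\n").split("\t")[1:]]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            gene = fields[0].strip()
            cells = fields[1:]
            if len(cells) != len(experiment_ids):
                raise FormatError(
                    f"{path}:{lineno}: ragged row for gene {gene!r} "
                    f"({len(cells)} values, expected {len(experiment_ids)})"
                )
            parsed = []
            for j, cell in enumerate(cells):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {cell.strip()!r} for gene "
                        f"{gene!r}, experiment {experiment_ids[j]!r}"
                    ) from None
            if gene in gene_ids:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            gene_ids.append(gene)
            rows.append(parsed)
    if not gene_ids:
        raise FormatError(f"{path}: no gene rows")
    return ExpressionMatrix(gene_ids, experiment_ids, np.array(rows, dtype=float))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


# ---------------------------------------------------------------------------
# Regulatory networks and gold standards
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryNetwork:
    """Directed, optionally signed, TF -> target edge set over a gene universe.

    ``edges`` maps (tf, target) to a sign: +1 activation, -1 repression.
    Self-loops are rejected; an edge appears at most once.
    """

    genes: set[str]
    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = {str(g).strip() for g in self.genes}
        clean: dict[tuple[str, str], int] = {}
        for (tf, target), sign in dict(self.edges).items():
            tf, target = str(tf).strip(), str(target).strip()
            if tf == target:
                raise FormatError(f"self-loop {tf!r} -> {target!r} not allowed")
            if sign not in (+1, -1):
                raise FormatError(f"edge sign must be +1 or -1, got {sign!r}")
            if tf not in self.genes or target not in self.genes:
                raise FormatError(f"edge {tf!r} -> {target!r} references unknown gene")
            clean[(tf, target)] = sign
        self.edges = clean

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def tfs(self) -> list[str]:
        """Genes with out-degree >= 1, sorted."""
        return sorted({tf for tf, _ in self.edges})

    def targets_of(self, tf: str) -> set[str]:
        return {t for (s, t) in self.edges if s == tf}

    def regulators_of(self, gene: str) -> list[tuple[str, int]]:
        return sorted((s, sign) for (s, t), sign in self.edges.items() if t == gene)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.genes))
        for (tf, target), sign in self.edges.items():
            g.add_edge(tf, target, sign=sign)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "RegulatoryNetwork":
        edges = {(u, v): int(d.get("sign", +1)) for u, v, d in g.edges(data=True)}
        return cls(set(g.nodes), edges)


def read_gold_standard(path, gene_universe: set[str] | None = None) -> RegulatoryNetwork:
    """Read a three-column gold standard: ``tf<TAB>target<TAB>flag``.

    Flag-1 lines are edges; flag-0 lines are explicit non-edges and only
    contribute their gene ids to the universe.  Unsigned edges get sign +1.
    """
    genes = {str(g).strip() for g in gene_universe} if gene_universe else set()
    edges: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [tok.strip() for tok in line.rstrip("\n").split("\t")]
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            tf, target, flag = fields[0], fields[1], fields[2]
            if flag not in ("0", "1"):
                raise FormatError(f"{path}:{lineno}: flag must be 0 or 1, got {flag!r}")
            if tf == target:
                raise FormatError(f"{path}:{lineno}: self-loop {tf!r} -> {target!r}")
            genes.update((tf, target))
            if flag == "1":
                edges[(tf, target)] = +1
    return RegulatoryNetwork(genes, edges)


def write_gold_standard(network: RegulatoryNetwork, path) -> None:
    """Write flag-1 lines for every edge, sorted for determinism."""
    with open(path, "w") as fh:
        for tf, target in sorted(network.edges):
            fh.write(f"{tf}\t{target}\t1\n")


# ---------------------------------------------------------------------------
# Training labels
# ---------------------------------------------------------------------------


@dataclass
class LabelSet:
    """Closed-world training labels for one TF's local model."""

    tf: str
    positives: set[str]
    negatives: set[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise FormatError(f"labels for {self.tf!r}: positives overlap negatives")
        if self.tf in self.positives or self.tf in self.negatives:
            raise FormatError(f"labels for {self.tf!r}: TF cannot be its own example")


def build_labels(network: RegulatoryNetwork, tf: str) -> LabelSet:
    """Positives = known targets of ``tf``; negatives = every other gene.

    The TF itself is excluded from both classes.  Any gene not curated as a
    target is assumed to be a negative (closed world).
    """
    if tf not in network.genes:
        raise KeyError(f"TF {tf!r} not in network gene universe")
    positives = network.targets_of(tf)
    negatives = network.genes - positives - {tf}
    return LabelSet(tf, positives, negatives)


# ---------------------------------------------------------------------------
# Ranked edge score tables
# ---------------------------------------------------------------------------


@dataclass
class EdgeScoreTable:
    """Scored (tf, gene) candidate pairs; higher score = stronger candidate.

    Scores may be -inf (a sentinel ranking untrainable TFs' candidates last)
    but never NaN, and no (tf, gene) pair appears twice.
    """

    entries: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        clean = []
        for tf, gene, score in self.entries:
            tf, gene, score = str(tf), str(gene), float(score)
            if tf == gene:
                raise FormatError(f"self-pair ({tf!r}, {gene!r}) not allowed")
            if (tf, gene) in seen:
                raise FormatError(f"duplicate pair ({tf!r}, {gene!r})")
            if math.isnan(score):
                raise FormatError(f"NaN score for pair ({tf!r}, {gene!r})")
            seen.add((tf, gene))
            clean.append((tf, gene, score))
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def sorted_entries(self) -> list[tuple[str, str, float]]:
        """Descending by score; ties broken by (tf, gene) lexicographically."""
        return sorted(self.entries, key=lambda e: (-e[2], e[0], e[1]))

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {(tf, gene): score for tf, gene, score in self.entries}


def write_ranked_edges(table: EdgeScoreTable, path) -> None:
    with open(path, "w") as fh:
        for tf, gene, score in table.sorted_entries():
            fh.write(f"{tf}\t{gene}\t{score:.17g}\n")


def read_ranked_edges(path) -> EdgeScoreTable:
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            entries.append((fields[0], fields[1], float(fields[2])))
    return EdgeScoreTable(entries)


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None
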