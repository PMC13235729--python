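"""Domain containers and file I/O shared by every pipeline stage.

Expression matrices are genes x samples on the log2(TPM+1) scale, carried
in a :class:`ExpressionCohort` together with per-gene class labels
(lncRNA / immune / SSG / other) and per-sample metadata (tumor/normal
condition, tumor purity, survival).  Weighted undirected networks (PPI or
co-expression) are carried in :class:`WeightedNetwork`, which exposes the
column-stochastic random-walk operator used by the propagation stages.

File formats are deliberately plain: TSV matrices, two-column class
tables, GMT gene sets and three-column edge lists (STRING-style
``node1 node2 combined_score``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

GENE_CLASSES = ("lncRNA", "immune", "SSG", "other")


class CohortError(ValueError):
    """Raised for malformed cohort inputs (duplicates, non-numeric cells...)."""


@dataclass
class ExpressionCohort:
    """Genes x samples expression matrix with gene classes and sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns sample ids, log2(TPM+1) scale.
    gene_class
        Series mapping gene id -> one of ``GENE_CLASSES``. Genes absent from
        the mapping are classed ``"other"``.
    condition
        Optional Series mapping sample -> ``"tumor"`` / ``"normal"``.
    purity
        Optional Series mapping sample -> tumor purity in [0, 1].
    survival
        Optional DataFrame indexed by sample with columns ``time`` (>= 0)
        and ``event`` (0/1).
    """

    values: pd.DataFrame
    gene_class: pd.Series
    condition: pd.Series | None = None
    purity: pd.Series | None = None
    survival: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        dup = self.values.index[self.values.index.duplicated()].unique()
        if len(dup):
            raise CohortError(f"duplicate gene ids: {', '.join(map(str, dup))}")
        if self.values.isna().any().any():
            stacked = self.values.stack(future_stack=True)
            bad = stacked[stacked.isna()].index[0]
            raise CohortError(
                f"missing/non-numeric value for gene {bad[0]!r}, sample {bad[1]!r}"
            )
        # every gene gets exactly one class; unknown genes default to "other"
        self.gene_class = self.gene_class.reindex(self.values.index).fillna("other")
        bad_classes = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad_classes:
            raise CohortError(f"unknown gene classes: {sorted(bad_classes)}")
        if self.purity is not None:
            self.purity = self.purity.reindex(self.values.columns).astype(float)
            p = self.purity.dropna()
            if ((p < 0) | (p > 1)).any():
                raise CohortError("purity values must lie in [0, 1]")
        if self.condition is not None:
            self.condition = self.condition.reindex(self.values.columns)
        if self.survival is not None:
            self.survival = self.survival.reindex(self.values.columns)

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.gene_class.index[self.gene_class == cls])

    def expression(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionCohort":
        genes = list(genes)
        return ExpressionCohort(
            values=self.values.loc[genes],
            gene_class=self.gene_class.loc[genes],
            condition=self.condition,
            purity=self.purity,
            survival=self.survival,
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionCohort":
        samples = list(samples)
        return ExpressionCohort(
            values=self.values[samples],
            gene_class=self.gene_class,
            condition=None if self.condition is None else self.condition.loc[samples],
            purity=None if self.purity is None else self.purity.loc[samples],
            survival=None if self.survival is None else self.survival.loc[samples],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. stemness signatures, immune pathways)."""

    sets: dict[str, set[str]]
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Drop members absent from *universe*; skip sets left empty (warn)."""
        universe = set(universe)
        kept: dict[str, set[str]] = {}
        for name, members in self.sets.items():
            inter = members & universe
            if inter:
                kept[name] = inter
            else:
                warnings.warn(f"gene set {name!r} has no members in cohort; skipped")
        return GeneSetCollection(kept, {k: self.description.get(k, "") for k in kept})


class WeightedNetwork:
    """Undirected weighted graph with a column-stochastic transition operator.

    The transition matrix A normalizes each node's outgoing weight to 1
    (column j = neighbors of node j, weighted by edge weight / weighted
    degree), which is the random-walk operator used by restart propagation.
    Isolated nodes receive an identity self-transition column so that A stays
    stochastic and no probability mass leaks.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] | None = None
    ) -> "WeightedNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v, w in edges:
            if u == v:
                warnings.warn(f"self-loop on {u!r} skipped")
                continue
            if w <= 0:
                raise ValueError(f"non-positive edge weight {w} on ({u}, {v})")
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, float(d["weight"])))
        return sorted(out)

    def transition_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Column-stochastic operator A and the node order it is indexed by."""
        order = self.nodes
        n = len(order)
        idx = {node: i for i, node in enumerate(order)}
        A = np.zeros((n, n))
        for u, v, d in self.graph.edges(data=True):
            w = float(d["weight"])
            A[idx[u], idx[v]] = w
            A[idx[v], idx[u]] = w
        colsums = A.sum(axis=0)
        for j in range(n):
            if colsums[j] > 0:
                A[:, j] /= colsums[j]
            else:
                A[j, j] = 1.0  # isolated node: identity self-transition
        return A, order

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class DEResult:
    """Per-gene differential-expression summary.

    ``passes`` is the joint screen |log2fc| > lfc_threshold AND
    fdr < fdr_threshold.
    """

    table: pd.DataFrame  # index gene; columns log2fc, p, fdr, passes
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05

    def passing_genes(self) -> list[str]:
        return list(self.table.index[self.table["passes"]])


# -- readers / writers ---------------------------------------------------------


def read_expression(path, class_path=None, meta_path=None) -> ExpressionCohort:
    """Read an expression TSV (genes in rows, header = sample ids).

    ``class_path`` is a two-column TSV (gene, class); genes it omits are
    classed ``"other"``.  ``meta_path`` is a TSV with columns ``sample`` and
    any of ``condition``, ``purity``, ``time``, ``event``.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    dup = raw.index[raw.index.duplicated()].unique()
    if len(dup):
        raise CohortError(f"duplicate gene ids in {path}: {', '.join(map(str, dup))}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        stacked = values.stack(future_stack=True)
        bad = stacked[stacked.isna()].index[0]
        raise CohortError(
            f"non-numeric cell in {path} at gene {bad[0]!r}, sample {bad[1]!r}"
        )

    if class_path is not None:
        cls = pd.read_csv(
            class_path, sep="\t", header=None, names=["gene", "class"], comment="#"
        )
        gene_class = cls.set_index("gene")["class"]
    else:
        gene_class = pd.Series(dtype=object)

    condition = purity = survival = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t").set_index("sample")
        if "condition" in meta:
            condition = meta["condition"]
        if "purity" in meta:
            purity = meta["purity"].astype(float)
        if {"time", "event"} <= set(meta.columns):
            survival = meta[["time", "event"]].astype(float)

    return ExpressionCohort(values, gene_class, condition, purity, survival)


def write_expression(cohort: ExpressionCohort, path, class_path=None, meta_path=None) -> None:
    cohort.values.to_csv(path, sep="\t", index_label="gene")
    if class_path is not None:
        cohort.gene_class.to_frame().to_csv(class_path, sep="\t", header=False)
    if meta_path is not None:
        meta = pd.DataFrame(index=pd.Index(cohort.sample_ids, name="sample"))
        if cohort.condition is not None:
            meta["condition"] = cohort.condition
        if cohort.purity is not None:
            meta["purity"] = cohort.purity
        if cohort.survival is not None:
            meta["time"] = cohort.survival["time"]
            meta["event"] = cohort.survival["event"]
        meta.to_csv(meta_path, sep="\t")


def tpm_log_transform(tpm) -> np.ndarray:
    """Elementwise log2(x + 1) of a nonnegative TPM matrix."""
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be nonnegative")
    return np.log2(arr + 1.0)


def filter_low_expression(cohort: ExpressionCohort, zero_fraction: float = 0.7) -> ExpressionCohort:
    """Drop genes with zero expression in strictly more than *zero_fraction* of samples."""
    if not 0 < zero_fraction < 1:
        raise ValueError("zero_fraction must lie strictly between 0 and 1")
    frac_zero = (cohort.values == 0).sum(axis=1) / cohort.n_samples
    keep = cohort.values.index[frac_zero <= zero_fraction]
    if len(keep) == 0:
        warnings.warn("low-expression filter removed every gene")
    return cohort.subset_genes(keep)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated members)."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 fields, got {len(fields)}")
            name, description, *members = fields
            sets[name] = {m for m in members if m}
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, collection.description.get(name, "")] + members) + "\n")


def read_edge_list(path, min_score: float = 700.0, max_score: float = 1000.0) -> WeightedNetwork:
    """Read a STRING-style edge list TSV (node1, node2, combined_score).

    Edges with score strictly greater than *min_score* are kept with weight
    score / *max_score*; duplicated pairs keep the maximum weight.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["u", "v", "score"], comment="#")
    edges = []
    for u, v, score in df.itertuples(index=False):
        if u == v:
            warnings.warn(f"self-loop row ({u}, {v}) skipped")
            continue
        if score > min_score:
            edges.append((str(u), str(v), float(score) / max_score))
    if not edges:
        warnings.warn("no edges passed the score threshold; network is empty")
    return WeightedNetwork.from_edges(edges)


def write_edge_list(network: WeightedNetwork, path, max_score: float = 1000.0) -> None:
    with open(path, "w") as fh:
        for u, v, w in network.edges():
            fh.write(f"{u}\t{v}\t{w * max_score:.6g}\n")
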