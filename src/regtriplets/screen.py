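"""Candidate-gene screening: differential expression, network propagation.

Two propagation primitives drive the screen.  Random walk with restart
(RWR) on a protein interaction network nominates stemness signature genes
(SSGs) by proximity to seed stemness factors; personalized PageRank on a
co-expression network then prioritizes the lncRNAs and immune genes most
closely tied to the SSGs.  Both use the same column-stochastic operator A,

    p(t+1) = (1 - r) A p(t) + r p(0),

iterated to an L1 fixed point, with restart mass p(0) uniform over the
seed set; PageRank with damping d is the same fixed point with r = 1 - d.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEResult, ExpressionCohort, WeightedNetwork
from .triplets import bh_adjust


@dataclass
class PropagationResult:
    """Converged propagation scores over network nodes."""

    scores: pd.Series      # node -> score, sums to 1
    restart: float
    seeds: frozenset
    iterations: int
    residual: float


@dataclass
class ScreenOutput:
    """Everything the triplet-assembly stage needs from the screen."""

    de: DEResult
    ssg_candidates: list[str]
    prioritized_lncRNAs: list[str]
    prioritized_immune: list[str]
    coexpression: WeightedNetwork
    propagation: PropagationResult | None = None


def differential_expression(
    cohort: ExpressionCohort, lfc_threshold: float = 1.0, fdr_threshold: float = 0.05
) -> DEResult:
    """Welch's t per gene between tumor and normal samples, BH-adjusted.

    log2fc is mean(tumor) - mean(normal) on the log2 scale;
    ``passes`` requires |log2fc| > lfc_threshold and fdr < fdr_threshold.
    """
    if cohort.condition is None:
        raise ValueError("cohort has no condition labels")
    tumor = cohort.condition.index[cohort.condition == "tumor"]
    normal = cohort.condition.index[cohort.condition == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(tumor)} tumor / {len(normal)} normal"
        )
    tv = cohort.values[tumor].to_numpy(dtype=float)
    nv = cohort.values[normal].to_numpy(dtype=float)
    log2fc = tv.mean(axis=1) - nv.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(tv, nv, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_adjust(p)
    passes = (np.abs(log2fc) > lfc_threshold) & (fdr < fdr_threshold)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "passes": passes}, index=cohort.values.index
    )
    return DEResult(table, lfc_threshold, fdr_threshold)


def rwr(
    network: WeightedNetwork,
    seeds,
    r: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> PropagationResult:
    """Random walk with restart from a uniform seed distribution."""
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    missing = seeds - set(network.graph.nodes)
    if missing:
        raise ValueError(f"seeds not in network: {sorted(missing)}")
    if not 0 < r <= 1:
        raise ValueError("restart probability must lie in (0, 1]")

    A, order = network.transition_matrix()
    idx = {node: i for i, node in enumerate(order)}
    p0 = np.zeros(len(order))
    for s in seeds:
        p0[idx[s]] = 1.0 / len(seeds)

    p = p0.copy()
    residual = math.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p_next = (1.0 - r) * (A @ p) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            break
    else:
        warnings.warn(f"RWR did not reach tol={tol} in {max_iter} iterations")
    return PropagationResult(
        scores=pd.Series(p, index=order),
        restart=r,
        seeds=seeds,
        iterations=iterations,
        residual=residual,
    )


def select_top_fraction(
    result: PropagationResult, fraction: float = 0.05, exclude_seeds: bool = True
) -> list[str]:
    """Top ceil(fraction x eligible) nodes by score; ties broken by id."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    scores = result.scores
    if exclude_seeds:
        scores = scores.drop(labels=list(result.seeds))
    k = math.ceil(fraction * len(scores))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [node for node, _ in ranked[:k]]


def build_coexpression_network(
    cohort: ExpressionCohort,
    genes=None,
    classes: tuple[str, ...] = ("lncRNA", "immune", "SSG"),
    min_abs_r: float = 0.3,
    fdr: float = 0.05,
) -> WeightedNetwork:
    """Pearson co-expression network over the given genes.

    Edges kept when |r| >= min_abs_r and the BH-adjusted correlation-test
    p-value is below *fdr*; edge weight is |r|, the sign retained as a
    ``sign`` edge attribute.  Constant genes are skipped with a warning.
    """
    if cohort.n_samples < 10:
        raise ValueError("need >= 10 samples for a co-expression network")
    if genes is None:
        genes = [g for g in cohort.gene_ids if cohort.gene_class[g] in classes]
    genes = [g for g in genes if cohort.gene_class[g] in classes]
    X = cohort.values.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        for g in np.asarray(genes)[constant]:
            warnings.warn(f"gene {g!r} is constant; its edges are skipped")
    keep = ~constant
    genes = [g for g, k in zip(genes, keep) if k]
    X = X[keep]
    n = X.shape[1]
    m = len(genes)

    net = WeightedNetwork.from_edges([], nodes=genes)
    if m < 2:
        return net

    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    R = (Z @ Z.T) / n
    iu, ju = np.triu_indices(m, k=1)
    r = np.clip(R[iu, ju], -0.999999999, 0.999999999)
    # t-test for Pearson correlation, n-2 df
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    q = bh_adjust(p)
    mask = (np.abs(r) >= min_abs_r) & (q < fdr)
    for i, j, rv in zip(iu[mask], ju[mask], r[mask]):
        net.graph.add_edge(genes[i], genes[j], weight=float(abs(rv)), sign=int(np.sign(rv)))
    return net


def pagerank_prioritize(
    network: WeightedNetwork,
    ssg_seeds,
    gene_class: pd.Series,
    top_k: int = 200,
    damping: float = 0.85,
) -> tuple[list[str], list[str]]:
    """Personalized PageRank from SSG seeds; top-k lncRNAs and immune genes.

    The personalization vector puts uniform mass on the SSG seeds and zero
    elsewhere; the fixed point is computed with the restart-walk iteration
    at r = 1 - damping on the same column-stochastic operator.
    """
    result = rwr(network, ssg_seeds, r=1.0 - damping)
    out: dict[str, list[str]] = {}
    for cls in ("lncRNA", "immune"):
        members = [g for g in result.scores.index if gene_class.get(g) == cls]
        if not members:
            warnings.warn(f"no {cls} nodes in network; empty prioritized list")
            out[cls] = []
            continue
        ranked = sorted(
            ((g, result.scores[g]) for g in members), key=lambda kv: (-kv[1], kv[0])
        )
        out[cls] = [g for g, _ in ranked[:top_k]]
    return out["lncRNA"], out["immune"]


def run_screen(
    cohort: ExpressionCohort,
    ppi: WeightedNetwork | None = None,
    stemness_seeds=None,
    top_fraction: float = 0.05,
    restart: float = 0.85,
    top_k: int = 200,
    min_abs_r: float = 0.3,
    coexpr_fdr: float = 0.05,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> ScreenOutput:
    """Full screening stage: DE -> (optional) RWR SSG nomination ->
    co-expression network -> PageRank prioritization.

    When a PPI network and seed stemness factors are given, SSG candidates
    are the RWR top fraction intersected with differentially expressed SSGs;
    otherwise all differentially expressed SSG-classed genes are used.
    """
    de = differential_expression(cohort, lfc_threshold, fdr_threshold)
    de_genes = set(de.passing_genes())

    propagation = None
    ssg_all = [g for g in cohort.gene_ids if cohort.gene_class[g] == "SSG"]
    if ppi is not None and stemness_seeds:
        propagation = rwr(ppi, stemness_seeds, r=restart)
        nominated = set(select_top_fraction(propagation, top_fraction)) | set(stemness_seeds)
        ssg_candidates = sorted(g for g in ssg_all if g in de_genes and g in nominated)
    else:
        ssg_candidates = sorted(g for g in ssg_all if g in de_genes)

    net_genes = [
        g
        for g in cohort.gene_ids
        if g in de_genes and cohort.gene_class[g] in ("lncRNA", "immune", "SSG")
    ]
    # co-expression is a within-tumor quantity: pooling tumor and normal
    # samples would let the tumor/normal mean shift correlate every DE gene
    # with every other
    tumor_ids = cohort.condition.index[cohort.condition == "tumor"]
    coexpr = build_coexpression_network(
        cohort.subset_samples(tumor_ids), genes=net_genes,
        min_abs_r=min_abs_r, fdr=coexpr_fdr,
    )
    seeds_in_net = [g for g in ssg_candidates if g in coexpr.graph]
    if seeds_in_net:
        lncs, imms = pagerank_prioritize(coexpr, seeds_in_net, cohort.gene_class, top_k=top_k)
    else:
        warnings.warn("no SSG candidate present in the co-expression network")
        lncs, imms = [], []
    return ScreenOutput(
        de=de,
        ssg_candidates=ssg_candidates,
        prioritized_lncRNAs=lncs,
        prioritized_immune=imms,
        coexpression=coexpr,
        propagation=propagation,
    )
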