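"""Triplet candidate assembly by purity-adjusted weighted partial correlation.

For every prioritized (lncRNA, SSG) pair the stage

1. computes first-order partial correlations with each immune gene,
   controlling for tumor purity:

       pcc = (R_xy - R_xp R_yp) / sqrt((1 - R_xp^2)(1 - R_yp^2)),

   with significance from t = pcc sqrt((n-3)/(1-pcc^2)) on n-3 df;
2. weights immune genes by the enrichment score (ES) of the most
   significant immune pathway containing them, from a weighted
   Kolmogorov-Smirnov running-sum enrichment (exponent 1) over genes
   ranked by their mean absolute partial correlation with the pair;
3. sums the signed -log10 p evidence into the weighted partial-correlation
   (WPC) score

       WPC = sum_i beta_i (-log10(P_i^(1)) sign(cor_i^(1))
                           - log10(P_i^(2)) sign(cor_i^(2)));

4. estimates significance by permuting the lncRNA's sample labels
   (breaking its links to SSG and immune genes while preserving the
   SSG-immune-purity alignment) and counting two-sided exceedances,
   p = N / n_perm, followed by Benjamini-Hochberg adjustment across pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionCohort, GeneSetCollection


@dataclass
class PartialCorrelation:
    pcc: float
    p: float
    n: int
    r_xy: float
    r_xp: float
    r_yp: float


@dataclass
class WpcTerm:
    """One immune gene's contribution to a pair's WPC score."""

    gene: str
    beta: float
    p1: float      # partial-correlation p, lncRNA vs immune gene
    cor1: float
    p2: float      # partial-correlation p, SSG vs immune gene
    cor2: float


@dataclass
class EnrichmentWeights:
    beta: dict[str, float]
    pathway_es: dict[str, tuple[float, float]]  # pathway -> (ES, p)
    ranking_used: str = "mean absolute purity-adjusted partial correlation with the pair"


@dataclass
class TripletCandidate:
    lncRNA: str
    ssg: str
    immune_genes: list[str]
    wpc: float
    perm_p: float
    fdr: float = float("nan")
    per_gene_terms: list[WpcTerm] = field(default_factory=list)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xz = x - x.mean()
    yz = y - y.mean()
    denom = np.sqrt((xz @ xz) * (yz @ yz))
    if denom == 0:
        raise ValueError("constant vector in correlation")
    return float(xz @ yz / denom)


def partial_correlation(x, y, covariate) -> PartialCorrelation:
    """First-order partial correlation of x and y given one covariate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = x.size
    if y.size != n or z.size != n:
        raise ValueError("x, y and covariate must have equal length")
    if n < 4:
        raise ValueError("need n >= 4 for a first-order partial correlation")
    if np.ptp(z) == 0:
        raise ValueError("covariate is constant")
    r_xy = _pearson(x, y)
    r_xp = _pearson(x, z)
    r_yp = _pearson(y, z)
    if abs(r_xp) >= 1.0 or abs(r_yp) >= 1.0:
        raise ValueError("degenerate partial correlation: |r with covariate| = 1")
    pcc = (r_xy - r_xp * r_yp) / np.sqrt((1.0 - r_xp**2) * (1.0 - r_yp**2))
    pcc = float(np.clip(pcc, -1.0, 1.0))
    p = _pcor_pvalue(np.array([pcc]), n)[0]
    return PartialCorrelation(pcc=pcc, p=float(p), n=n, r_xy=r_xy, r_xp=r_xp, r_yp=r_yp)


def _pcor_pvalue(pcc: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a first-order partial correlation on n-3 df."""
    pcc = np.clip(pcc, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = pcc * np.sqrt((n - 3) / np.maximum(1.0 - pcc**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 3)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant vector in correlation")
    return (X - mu) / sd


def _pcor_block(Xz: np.ndarray, Yz: np.ndarray, pz: np.ndarray) -> np.ndarray:
    """Partial correlations of every row of Xz with every row of Yz given pz.

    All inputs are row-standardized; returns an (X rows x Y rows) matrix.
    """
    n = pz.size
    r_xy = (Xz @ Yz.T) / n
    r_xp = (Xz @ pz) / n
    r_yp = (Yz @ pz) / n
    denom = np.sqrt(
        np.clip(1.0 - r_xp**2, 1e-300, None)[:, None]
        * np.clip(1.0 - r_yp**2, 1e-300, None)[None, :]
    )
    return np.clip((r_xy - np.outer(r_xp, r_yp)) / denom, -1.0, 1.0)


# -- GSEA-style enrichment weights --------------------------------------------


def _running_sum_es(membership: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Signed enrichment score(s) of the weighted KS running sum.

    ``membership`` is a boolean array (..., N) over a ranked gene list,
    ``weights`` the (nonnegative) ranking weights in the same order.  Hits
    step up by w_i / sum(hit weights), misses step down by 1 / (N - m).
    The ES is the running-sum value of largest magnitude.
    """
    membership = np.atleast_2d(membership)
    N = membership.shape[-1]
    m = membership.sum(axis=-1, keepdims=True)
    if ((m == 0) | (m == N)).any():
        raise ValueError("pathway must be a proper nonempty subset of the ranked list")
    w_hit = np.where(membership, weights, 0.0)
    hit_norm = w_hit.sum(axis=-1, keepdims=True)
    # degenerate all-zero hit weights: fall back to unweighted steps
    w_hit = np.where(hit_norm > 0, w_hit, membership.astype(float))
    hit_norm = w_hit.sum(axis=-1, keepdims=True)
    steps = w_hit / hit_norm - (~membership) / (N - m)
    rs = np.cumsum(steps, axis=-1)
    idx = np.argmax(np.abs(rs), axis=-1)
    return rs[np.arange(rs.shape[0]), idx]


def enrichment_weights(
    cohort: ExpressionCohort,
    pair: tuple[str, str],
    immune_pathways: GeneSetCollection,
    n_gsea_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> EnrichmentWeights:
    """Pair-specific immune-gene weights from pathway enrichment.

    Immune genes are ranked by the mean of their two absolute purity-adjusted
    partial correlations (with the lncRNA and with the SSG).  Each pathway's
    ES gets a gene-label permutation p; beta_i is the ES of the most
    significant enriched pathway (p < alpha) containing gene i, else 0.
    """
    lnc, ssg = pair
    immune_genes = sorted(cohort.genes_of_class("immune"))
    if not immune_genes:
        raise ValueError("cohort contains no immune-classed genes")
    if cohort.purity is None:
        raise ValueError("cohort has no tumor purity; required for partial correlation")

    pz = _standardize_rows(cohort.purity.to_numpy(dtype=float)[None, :])[0]
    Mz = _standardize_rows(cohort.values.loc[immune_genes].to_numpy(dtype=float))
    Lz = _standardize_rows(cohort.expression(lnc)[None, :])
    Sz = _standardize_rows(cohort.expression(ssg)[None, :])
    metric = 0.5 * (
        np.abs(_pcor_block(Mz, Lz, pz)[:, 0]) + np.abs(_pcor_block(Mz, Sz, pz)[:, 0])
    )

    order = sorted(range(len(immune_genes)), key=lambda i: (-metric[i], immune_genes[i]))
    ranked_genes = [immune_genes[i] for i in order]
    ranked_w = metric[np.array(order)]
    N = len(ranked_genes)
    pos = {g: i for i, g in enumerate(ranked_genes)}

    restricted = immune_pathways.restrict(ranked_genes)
    rng = np.random.default_rng(seed)
    pathway_es: dict[str, tuple[float, float]] = {}
    for name in sorted(restricted.sets):
        members = restricted.sets[name]
        if len(members) == N:
            warnings.warn(f"pathway {name!r} covers every immune gene; skipped")
            continue
        membership = np.zeros(N, dtype=bool)
        for g in members:
            membership[pos[g]] = True
        es = float(_running_sum_es(membership, ranked_w)[0])
        # gene-label permutation null: shuffle membership over rank positions
        perm_member = np.zeros((n_gsea_perm, N), dtype=bool)
        for b in range(n_gsea_perm):
            perm_member[b, rng.choice(N, size=len(members), replace=False)] = True
        null_es = _running_sum_es(perm_member, ranked_w)
        if es >= 0:
            p = float(np.mean(null_es >= es))
        else:
            p = float(np.mean(null_es <= es))
        pathway_es[name] = (es, p)

    beta: dict[str, float] = {g: 0.0 for g in immune_genes}
    for g in immune_genes:
        hits = [
            (p, -abs(es), name, es)
            for name, (es, p) in pathway_es.items()
            if p < alpha and g in restricted.sets[name]
        ]
        if hits:
            beta[g] = min(hits)[3]
    return EnrichmentWeights(beta=beta, pathway_es=pathway_es)


# -- WPC score and permutation null -------------------------------------------


def wpc_score(per_gene_terms, p_floor: float = 1e-4) -> float:
    """Weighted partial-correlation score of a pair.

    WPC = sum_i beta_i (-log10(P1) sign(cor1) - log10(P2) sign(cor2)).
    Exact-zero p-values are floored at *p_floor* with a warning to keep the
    score finite.
    """
    total = 0.0
    for term in per_gene_terms:
        p1, p2 = term.p1, term.p2
        if p1 <= 0:
            warnings.warn(f"p-value underflow for {term.gene}; floored at {p_floor}")
            p1 = p_floor
        if p2 <= 0:
            warnings.warn(f"p-value underflow for {term.gene}; floored at {p_floor}")
            p2 = p_floor
        total += term.beta * (
            -np.log10(p1) * np.sign(term.cor1) - np.log10(p2) * np.sign(term.cor2)
        )
    return float(total)


def wpc_terms(
    cohort: ExpressionCohort, pair: tuple[str, str], weights: EnrichmentWeights
) -> list[WpcTerm]:
    """Per-immune-gene WPC terms for genes with nonzero enrichment weight."""
    lnc, ssg = pair
    genes = sorted(g for g, b in weights.beta.items() if b != 0.0)
    if not genes:
        return []
    n = cohort.n_samples
    pz = _standardize_rows(cohort.purity.to_numpy(dtype=float)[None, :])[0]
    Mz = _standardize_rows(cohort.values.loc[genes].to_numpy(dtype=float))
    Lz = _standardize_rows(cohort.expression(lnc)[None, :])
    Sz = _standardize_rows(cohort.expression(ssg)[None, :])
    c1 = _pcor_block(Lz, Mz, pz)[0]
    c2 = _pcor_block(Sz, Mz, pz)[0]
    p1 = _pcor_pvalue(c1, n)
    p2 = _pcor_pvalue(c2, n)
    return [
        WpcTerm(gene=g, beta=weights.beta[g], p1=float(p1[i]), cor1=float(c1[i]),
                p2=float(p2[i]), cor2=float(c2[i]))
        for i, g in enumerate(genes)
    ]


def compute_wpc(
    cohort: ExpressionCohort, pair: tuple[str, str], weights: EnrichmentWeights,
    p_floor: float = 1e-4,
) -> tuple[float, list[WpcTerm]]:
    terms = wpc_terms(cohort, pair, weights)
    return wpc_score(terms, p_floor=p_floor), terms


def permutation_test(
    cohort: ExpressionCohort,
    pair: tuple[str, str],
    weights: EnrichmentWeights,
    n_perm: int = 1000,
    seed: int = 0,
    p_floor: float = 1e-4,
) -> tuple[float, np.ndarray]:
    """Empirical two-sided permutation p for a pair's WPC score.

    Only the lncRNA's sample labels are shuffled: this breaks the
    lncRNA-SSG and lncRNA-immune dependencies while keeping the SSG, immune
    and purity columns aligned.  p = N / n_perm where N counts permutations
    with |null WPC| >= |observed WPC| (enrichment weights held fixed).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    lnc, ssg = pair
    observed, terms = compute_wpc(cohort, pair, weights, p_floor=p_floor)
    if not terms:
        return 1.0, np.zeros(n_perm)

    genes = [t.gene for t in terms]
    beta = np.array([t.beta for t in terms])
    n = cohort.n_samples
    pz = _standardize_rows(cohort.purity.to_numpy(dtype=float)[None, :])[0]
    Mz = _standardize_rows(cohort.values.loc[genes].to_numpy(dtype=float))
    lnc_vec = cohort.expression(lnc)

    # fixed SSG-side evidence; flooring matches wpc_score (underflow only)
    ssg_part = np.array(
        [-np.log10(t.p2 if t.p2 > 0 else p_floor) * np.sign(t.cor2) for t in terms]
    )

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n))
    for b in range(n_perm):
        perms[b] = rng.permutation(lnc_vec)
    Lz = _standardize_rows(perms)
    c1 = _pcor_block(Lz, Mz, pz)             # n_perm x k
    p1 = _pcor_pvalue(c1, n)
    p1 = np.where(p1 > 0, p1, p_floor)
    lnc_part = -np.log10(p1) * np.sign(c1)
    null_scores = (beta[None, :] * (lnc_part + ssg_part[None, :])).sum(axis=1)

    n_exceed = int(np.sum(np.abs(null_scores) >= abs(observed)))
    return n_exceed / n_perm, null_scores


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assemble_triplets(
    cohort: ExpressionCohort,
    prioritized_lncRNAs,
    ssg_candidates,
    immune_pathways: GeneSetCollection,
    fdr_threshold: float = 0.05,
    n_perm: int = 1000,
    n_gsea_perm: int = 1000,
    seed: int = 0,
    p_floor: float | None = None,
) -> list[TripletCandidate]:
    """Score every prioritized lncRNA x SSG pair and keep FDR < threshold.

    Pairs whose enrichment weights are all zero contribute WPC = 0 and
    permutation p = 1 (they cannot be retained).  The immune genes with
    nonzero weight become the retained triplets' immune partners.
    """
    if p_floor is None:
        p_floor = 1.0 / (10.0 * n_perm)
    candidates: list[TripletCandidate] = []
    pairs = [(l, s) for l in sorted(prioritized_lncRNAs) for s in sorted(ssg_candidates)]
    for k, (lnc, ssg) in enumerate(pairs):
        pair_seed = (seed + 131071 * (k + 1)) % (2**31 - 1)
        weights = enrichment_weights(
            cohort, (lnc, ssg), immune_pathways, n_gsea_perm=n_gsea_perm, seed=pair_seed
        )
        wpc, terms = compute_wpc(cohort, (lnc, ssg), weights, p_floor=p_floor)
        if terms:
            perm_p, _ = permutation_test(
                cohort, (lnc, ssg), weights, n_perm=n_perm, seed=pair_seed + 1,
                p_floor=p_floor,
            )
        else:
            perm_p = 1.0
        candidates.append(
            TripletCandidate(
                lncRNA=lnc, ssg=ssg, immune_genes=[t.gene for t in terms],
                wpc=wpc, perm_p=perm_p, per_gene_terms=terms,
            )
        )
    fdr = bh_adjust([c.perm_p for c in candidates])
    retained = []
    for c, q in zip(candidates, fdr):
        c.fdr = float(q)
        if q < fdr_threshold:
            retained.append(c)
    if not retained:
        warnings.warn("no (lncRNA, SSG) pair survived the FDR threshold")
    return retained


def triplet_table(candidates: list[TripletCandidate], n_perm: int = 1000) -> pd.DataFrame:
    """Flat summary table (one row per retained pair).

    A permutation p of exactly 0 means no null draw reached the observed
    score; it is annotated as "< 1/n_perm" alongside the raw value.
    """
    return pd.DataFrame(
        [
            {
                "lncRNA": c.lncRNA,
                "SSG": c.ssg,
                "immune_genes": ";".join(c.immune_genes),
                "wpc": c.wpc,
                "perm_p": c.perm_p,
                "perm_p_label": (f"<{1.0 / n_perm:g}" if c.perm_p == 0
                                 else f"{c.perm_p:g}"),
                "fdr": c.fdr,
            }
            for c in candidates
        ]
    )


def per_gene_term_table(candidates: list[TripletCandidate]) -> pd.DataFrame:
    """Long-format table: one row per (pair, immune gene) WPC term."""
    rows = []
    for c in candidates:
        for t in c.per_gene_terms:
            rows.append(
                {
                    "lncRNA": c.lncRNA,
                    "SSG": c.ssg,
                    "immune_gene": t.gene,
                    "beta": t.beta,
                    "p_lnc": t.p1,
                    "cor_lnc": t.cor1,
                    "p_ssg": t.p2,
                    "cor_ssg": t.cor2,
                }
            )
    return pd.DataFrame(
        rows, columns=["lncRNA", "SSG", "immune_gene", "beta",
                       "p_lnc", "cor_lnc", "p_ssg", "cor_ssg"]
    )
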