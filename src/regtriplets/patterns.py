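"""Causal-pattern selection for regulatory triplets by BIC model comparison.

Each triplet (L = lncRNA, S = SSG, I = immune gene) is scored under four
candidate factorizations of the joint density, each a product of
linear-Gaussian conditionals fitted by maximum likelihood:

    IR  : P(L) P(S|L) P(I|L)        fork at the lncRNA
    CR  : P(L) P(I) P(S|L,I)        collider at the SSG
    LIS : P(L) P(I|L) P(S|I)        chain through the immune gene
    LSI : P(L) P(S|L) P(I|S)        chain through the SSG

Marginals carry 2 parameters (mean, variance), one-parent conditionals 3
(intercept, slope, variance) and the two-parent conditional 4, so every
pattern has k = 8 and the BIC ranking reduces to a likelihood ranking; the
BIC weights omega_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) are still
reported on the BIC scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PATTERN_ORDER = ("IR", "CR", "LIS", "LSI")

# factor lists: (child, parents) with children named 0=L, 1=S, 2=I
_FACTORIZATIONS: dict[str, tuple[tuple[int, tuple[int, ...]], ...]] = {
    "IR": ((0, ()), (1, (0,)), (2, (0,))),
    "CR": ((0, ()), (2, ()), (1, (0, 2))),
    "LIS": ((0, ()), (2, (0,)), (1, (2,))),
    "LSI": ((0, ()), (1, (0,)), (2, (1,))),
}


@dataclass
class PatternFit:
    """Likelihood, BIC, Delta and weight of each pattern, plus the winner."""

    loglik: dict[str, float]
    k: dict[str, int]
    bic: dict[str, float]
    delta: dict[str, float]
    weight: dict[str, float]
    selected: str
    n: int


def _gaussian_factor_loglik(child: np.ndarray, parents: np.ndarray | None) -> tuple[float, int]:
    """MLE Gaussian log-likelihood of one conditional factor and its k."""
    n = child.size
    if parents is None or parents.shape[1] == 0:
        resid = child - child.mean()
        k = 2
    else:
        X = np.column_stack([np.ones(n), parents])
        coef, *_ = np.linalg.lstsq(X, child, rcond=None)
        resid = child - X @ coef
        k = 2 + parents.shape[1]
    sigma2 = float(resid @ resid) / n
    scale = float(child @ child) / n + 1.0
    if sigma2 <= 1e-13 * scale or not np.isfinite(sigma2):
        raise ValueError("zero residual variance; degenerate likelihood")
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return loglik, k


def fit_pattern(L, S, I, pattern: str) -> tuple[float, int]:
    """Maximum log-likelihood and parameter count of one factorization."""
    if pattern not in _FACTORIZATIONS:
        raise ValueError(f"unknown pattern {pattern!r}")
    vecs = [np.asarray(v, dtype=float) for v in (L, S, I)]
    n = vecs[0].size
    if any(v.size != n for v in vecs):
        raise ValueError("L, S, I must have equal length")
    if n < 8:
        raise ValueError("need n >= 8 samples to fit a pattern")
    for v in vecs:
        if np.ptp(v) == 0:
            raise ValueError("constant expression vector; degenerate likelihood")
    total_ll = 0.0
    total_k = 0
    for child, parents in _FACTORIZATIONS[pattern]:
        P = np.column_stack([vecs[p] for p in parents]) if parents else None
        ll, k = _gaussian_factor_loglik(vecs[child], P)
        total_ll += ll
        total_k += k
    return total_ll, total_k


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, k ln(n) - 2 ln(L)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return k * np.log(n) - 2.0 * loglik


def bic_weights(bics: dict[str, float]) -> tuple[dict[str, float], dict[str, float]]:
    """Delta_i = BIC_i - BIC_min and weights omega_i = exp(-Delta_i/2) / sum.

    Invariant to adding a constant to every BIC; equal BICs give equal
    weights.
    """
    bic_min = min(bics.values())
    delta = {m: b - bic_min for m, b in bics.items()}
    raw = {m: np.exp(-0.5 * d) for m, d in delta.items()}
    total = sum(raw.values())
    weight = {m: r / total for m, r in raw.items()}
    return delta, weight


def select_pattern(L, S, I) -> PatternFit:
    """Fit all four patterns; pick the lowest BIC (ties -> IR<CR<LIS<LSI)."""
    n = np.asarray(L).size
    loglik: dict[str, float] = {}
    kmap: dict[str, int] = {}
    bics: dict[str, float] = {}
    for pat in PATTERN_ORDER:
        ll, k = fit_pattern(L, S, I, pat)
        loglik[pat] = ll
        kmap[pat] = k
        bics[pat] = bic(ll, k, n)
    delta, weight = bic_weights(bics)
    selected = min(PATTERN_ORDER, key=lambda pat: (bics[pat], PATTERN_ORDER.index(pat)))
    return PatternFit(
        loglik=loglik, k=kmap, bic=bics, delta=delta, weight=weight, selected=selected, n=n
    )
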