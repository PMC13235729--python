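"""Synthetic expression cohorts with planted regulatory triplets.

The generator emits linear-Gaussian structural-equation triplets under the
four candidate causal patterns relating an lncRNA (L), a stemness signature
gene (S) and an immune gene (I):

====  =======================  =============================================
IR    fork at L                L -> S, L -> I   (independent regulation)
CR    collider at S            L -> S <- I      (cooperative regulation)
LIS   chain via immune gene    L -> I -> S
LSI   chain via SSG            L -> S -> I
====  =======================  =============================================

A shared tumor-purity confounder enters the L (and, for CR, the I) equation
additively so that downstream purity-adjusted partial correlation has a real
confounder to remove.  Null background genes are i.i.d. normal.  Survival
times are exponential with a log-hazard linear in a triplet score, with
independent uniform censoring.

All randomness flows through ``numpy.random.default_rng``; each planted
triplet draws from its own sub-stream (seed offsetting) so that adding
triplets to a config does not perturb earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionCohort

PATTERNS = ("IR", "CR", "LIS", "LSI")

# offsets keeping derived seeds well separated (and below 2**31 for small bases)
_TRIPLET_SEED_STRIDE = 1009
_NULL_SEED_OFFSET = 7919
_PURITY_SEED_OFFSET = 104729
_NORMAL_SEED_OFFSET = 1299709
_SURVIVAL_SEED_OFFSET = 15485863


@dataclass
class TripletSpec:
    """Structural parameters of one planted triplet.

    ``n_immune`` controls the size of the planted immune module: the
    canonical immune gene follows the pattern's structural equation, and
    any additional module genes are noisy copies of it (sd
    ``module_noise_sd``).  Co-regulated immune modules are what pathway
    enrichment detects; a single immune gene per pair carries no set-level
    signal.
    """

    pattern: str
    a: float = 0.8
    b: float = 0.8
    noise_sd: float = 1.0
    purity_effect: float = 0.0
    n_immune: int = 1
    module_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_immune < 1:
            raise ValueError("n_immune must be >= 1")


@dataclass
class SyntheticCohortConfig:
    """Everything needed to generate one cohort deterministically."""

    n_samples: int = 300
    triplet_specs: list[TripletSpec] = field(default_factory=list)
    n_null_genes: int = 50
    seed: int = 0
    with_normal_block: bool = True
    n_normal: int | None = None        # default: n_samples
    de_shift: float = 1.5              # tumor-vs-normal mean shift (log2 units)
    baseline_expression: float = 5.0   # additive location on the log2 scale
    survival_baseline: float = 0.1     # exponential event rate at score 0
    survival_effect: float = 0.0       # log-hazard per unit triplet score
    censor_horizon: float = 30.0       # uniform censoring upper bound

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")


def generate_triplet(
    spec: TripletSpec, n: int, purity: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one (L, S, I) triplet of length-*n* expression vectors.

    L is standard normal plus ``purity_effect * purity``; S and I follow the
    pattern's structural equations with i.i.d. N(0, noise_sd^2) innovations.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    purity = np.asarray(purity, dtype=float)
    if purity.shape != (n,):
        raise ValueError("purity must have length n")
    rng = np.random.default_rng(seed)
    a, b, sd, c = spec.a, spec.b, spec.noise_sd, spec.purity_effect

    L = rng.standard_normal(n) + c * purity
    if spec.pattern == "IR":
        S = a * L + sd * rng.standard_normal(n)
        I = b * L + sd * rng.standard_normal(n)
    elif spec.pattern == "CR":
        I = rng.standard_normal(n) + c * purity
        S = a * L + b * I + sd * rng.standard_normal(n)
    elif spec.pattern == "LIS":
        I = a * L + sd * rng.standard_normal(n)
        S = b * I + sd * rng.standard_normal(n)
    else:  # LSI
        S = a * L + sd * rng.standard_normal(n)
        I = b * S + sd * rng.standard_normal(n)
    return L, S, I


def generate_cohort(config: SyntheticCohortConfig) -> tuple[ExpressionCohort, pd.DataFrame]:
    """Generate a cohort plus a provenance table for the planted genes.

    Planted triplet genes are named ``lnc_k`` / ``ssg_k`` / ``imm_k`` and
    classed accordingly; null genes are i.i.d. normal and classed round-robin
    over lncRNA/immune/SSG.  Purity is Beta(5, 2).  When
    ``with_normal_block`` is set, a matched block of normal samples with all
    gene means shifted down by ``de_shift`` is appended, so every gene is
    differentially expressed by construction and downstream screens operate
    on network structure rather than on the DE filter.
    """
    n = config.n_samples
    rng_purity = np.random.default_rng(config.seed + _PURITY_SEED_OFFSET)
    purity = rng_purity.beta(5.0, 2.0, size=n)

    rows: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    prov_records = []
    first_score: np.ndarray | None = None

    for k, spec in enumerate(config.triplet_specs):
        sub_seed = config.seed + _TRIPLET_SEED_STRIDE * (k + 1)
        L, S, I = generate_triplet(spec, n, purity, sub_seed)
        planted = [(f"lnc_{k}", L, "lncRNA", True), (f"ssg_{k}", S, "SSG", True),
                   (f"imm_{k}", I, "immune", True)]
        if spec.n_immune > 1:
            rng_mod = np.random.default_rng(sub_seed + 499)
            for j in range(1, spec.n_immune):
                copy = I + spec.module_noise_sd * rng_mod.standard_normal(n)
                planted.append((f"imm_{k}_m{j}", copy, "immune", False))
        for name, vec, cls, canonical in planted:
            rows[name] = vec
            classes[name] = cls
            prov_records.append(
                {
                    "gene": name,
                    "triplet": k,
                    "role": cls,
                    "canonical": canonical,
                    "pattern": spec.pattern,
                    "a": spec.a,
                    "b": spec.b,
                    "noise_sd": spec.noise_sd,
                    "purity_effect": spec.purity_effect,
                }
            )
        if first_score is None:
            first_score = (L + S + I) / 3.0

    rng_null = np.random.default_rng(config.seed + _NULL_SEED_OFFSET)
    null_classes = ("lncRNA", "immune", "SSG")
    for j in range(config.n_null_genes):
        name = f"null_{j}"
        rows[name] = rng_null.standard_normal(n)
        classes[name] = null_classes[j % 3]

    genes = list(rows)
    tumor_ids = [f"T{i:04d}" for i in range(n)]
    values = pd.DataFrame(
        np.vstack([rows[g] for g in genes]) + config.baseline_expression,
        index=genes,
        columns=tumor_ids,
    )
    condition = pd.Series("tumor", index=tumor_ids)
    purity_s = pd.Series(purity, index=tumor_ids)

    survival = None
    if config.survival_baseline > 0:
        score = first_score if first_score is not None else np.zeros(n)
        time, event = generate_survival(
            score,
            config.survival_baseline,
            config.survival_effect,
            config.seed + _SURVIVAL_SEED_OFFSET,
            censor_horizon=config.censor_horizon,
        )
        survival = pd.DataFrame({"time": time, "event": event}, index=tumor_ids)

    if config.with_normal_block:
        n_norm = config.n_normal if config.n_normal is not None else n
        rng_norm = np.random.default_rng(config.seed + _NORMAL_SEED_OFFSET)
        normal_ids = [f"N{i:04d}" for i in range(n_norm)]
        normal_vals = pd.DataFrame(
            rng_norm.standard_normal((len(genes), n_norm))
            + config.baseline_expression
            - config.de_shift,
            index=genes,
            columns=normal_ids,
        )
        values = pd.concat([values, normal_vals], axis=1)
        condition = pd.concat([condition, pd.Series("normal", index=normal_ids)])
        purity_s = pd.concat([purity_s, pd.Series(0.0, index=normal_ids)])
        if survival is not None:
            survival = survival.reindex(values.columns)

    cohort = ExpressionCohort(
        values=values,
        gene_class=pd.Series(classes),
        condition=condition,
        purity=purity_s,
        survival=survival,
    )
    provenance = pd.DataFrame(
        prov_records,
        columns=["gene", "triplet", "role", "canonical", "pattern", "a", "b",
                 "noise_sd", "purity_effect"],
    )
    return cohort, provenance


def immune_pathway_collection(
    cohort: ExpressionCohort,
    provenance: pd.DataFrame | None = None,
    n_null_pathways: int = 3,
    seed: int = 0,
):
    """Synthetic pathway gene sets over a cohort's immune genes.

    Each planted triplet's immune module becomes its own pathway (the
    co-regulated set that enrichment is supposed to detect); the remaining
    (null) immune genes are split round-robin into ``n_null_pathways``
    decoy pathways.
    """
    from .io import GeneSetCollection

    immune = sorted(cohort.genes_of_class("immune"))
    sets: dict[str, set[str]] = {}
    planted: set[str] = set()
    if provenance is not None and len(provenance):
        imm_rows = provenance[provenance["role"] == "immune"]
        for k, grp in imm_rows.groupby("triplet"):
            members = set(grp["gene"])
            sets[f"module_{k}"] = members
            planted |= members
    background = [g for g in immune if g not in planted]
    rng = np.random.default_rng(seed)
    rng.shuffle(background)
    for j, g in enumerate(background):
        sets.setdefault(f"pathway_{j % n_null_pathways}", set()).add(g)
    sets = {k: v for k, v in sets.items() if v}
    return GeneSetCollection(sets, {k: "synthetic immune pathway" for k in sets})


def generate_survival(
    scores: np.ndarray,
    baseline: float,
    effect: float,
    seed: int,
    censor_horizon: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival times with log-hazard linear in *scores*.

    time_i ~ Exp(rate = baseline * exp(effect * score_i)), censored at an
    independent Uniform(0, censor_horizon) draw; event = 1 if uncensored.
    """
    if baseline <= 0:
        raise ValueError("baseline rate must be positive")
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    rate = baseline * np.exp(effect * scores)
    latent = rng.exponential(1.0 / rate)
    censor = rng.uniform(0.0, censor_horizon, size=scores.shape)
    time = np.minimum(latent, censor)
    event = (latent <= censor).astype(int)
    return time, event


def generate_null_cohort(
    n_genes: int, n_samples: int, seed: int, with_normal_block: bool = False
) -> ExpressionCohort:
    """All-independent standard-normal cohort for null calibration.

    Genes are classed round-robin over lncRNA/immune/SSG.  With
    ``with_normal_block`` the samples are split half tumor / half normal
    (same distribution, no shift) so differential-expression nulls can be
    checked.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{j}" for j in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    values = pd.DataFrame(rng.standard_normal((n_genes, n_samples)), index=genes, columns=samples)
    classes = pd.Series(
        [("lncRNA", "immune", "SSG")[j % 3] for j in range(n_genes)], index=genes
    )
    condition = None
    if with_normal_block:
        half = n_samples // 2
        condition = pd.Series(
            ["tumor"] * half + ["normal"] * (n_samples - half), index=samples
        )
    purity = pd.Series(rng.beta(5.0, 2.0, size=n_samples), index=samples)
    return ExpressionCohort(values, classes, condition=condition, purity=purity)
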