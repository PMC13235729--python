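"""End-to-end orchestration: screen -> triplets -> patterns -> stability.

Glues the pipeline stages together on a single cohort.  Partial
correlations, pattern fits and stability are computed on tumor samples
only (purity is a tumor-sample covariate); the differential-expression
screen uses the full tumor + normal cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clinical import prognostic_screen
from .io import ExpressionCohort, GeneSetCollection, WeightedNetwork
from .patterns import PatternFit, select_pattern
from .screen import ScreenOutput, run_screen
from .stability import StabilityResult, bootstrap_stability
from .triplets import TripletCandidate, assemble_triplets, triplet_table


@dataclass
class PipelineResult:
    screen: ScreenOutput
    candidates: list[TripletCandidate]
    pattern_fits: dict[tuple[str, str, str], PatternFit] = field(default_factory=dict)
    stability: dict[tuple[str, str, str], StabilityResult] = field(default_factory=dict)
    prognostic: pd.DataFrame | None = None

    def pattern_table(self) -> pd.DataFrame:
        rows = []
        for (lnc, imm, ssg), fit in self.pattern_fits.items():
            row = {"lncRNA": lnc, "immune": imm, "SSG": ssg, "selected": fit.selected}
            for pat in fit.bic:
                row[f"bic_{pat}"] = fit.bic[pat]
                row[f"weight_{pat}"] = fit.weight[pat]
            rows.append(row)
        return pd.DataFrame(rows)

    def stability_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lncRNA": lnc,
                    "immune": imm,
                    "SSG": ssg,
                    "s_pair": r.s_pair,
                    "s_triplet": r.s_triplet,
                    "delta_s": r.delta_s,
                }
                for (lnc, imm, ssg), r in self.stability.items()
            ]
        )

    def triplet_table(self) -> pd.DataFrame:
        return triplet_table(self.candidates)


def tumor_subset(cohort: ExpressionCohort) -> ExpressionCohort:
    if cohort.condition is None:
        return cohort
    tumor = cohort.condition.index[cohort.condition == "tumor"]
    return cohort.subset_samples(tumor)


def run_pipeline(
    cohort: ExpressionCohort,
    immune_pathways: GeneSetCollection,
    ppi: WeightedNetwork | None = None,
    stemness_seeds=None,
    fdr_threshold: float = 0.05,
    n_perm: int = 1000,
    n_gsea_perm: int = 1000,
    bootstrap_B: int = 200,
    theta: float = 0.2,
    n_bins: int = 5,
    top_k: int = 200,
    seed: int = 0,
    with_survival: bool = False,
) -> PipelineResult:
    """Run every stage on one cohort and collect the per-triplet results."""
    screen_out = run_screen(cohort, ppi=ppi, stemness_seeds=stemness_seeds, top_k=top_k)
    tumor = tumor_subset(cohort)
    candidates = assemble_triplets(
        tumor,
        screen_out.prioritized_lncRNAs,
        screen_out.ssg_candidates,
        immune_pathways,
        fdr_threshold=fdr_threshold,
        n_perm=n_perm,
        n_gsea_perm=n_gsea_perm,
        seed=seed,
    )
    pattern_fits: dict[tuple[str, str, str], PatternFit] = {}
    stability: dict[tuple[str, str, str], StabilityResult] = {}
    counter = 0
    for c in candidates:
        L = tumor.expression(c.lncRNA)
        S = tumor.expression(c.ssg)
        for imm in c.immune_genes:
            counter += 1
            I = tumor.expression(imm)
            key = (c.lncRNA, imm, c.ssg)
            pattern_fits[key] = select_pattern(L, S, I)
            stability[key] = bootstrap_stability(
                L, S, I, B=bootstrap_B, theta=theta, n_bins=n_bins,
                seed=(seed + 524287 * counter) % (2**31 - 1),
            )
    prognostic = None
    if with_survival and tumor.survival is not None:
        triplets = sorted(pattern_fits)
        if triplets:
            prognostic = prognostic_screen(tumor, triplets)
    return PipelineResult(
        screen=screen_out,
        candidates=candidates,
        pattern_fits=pattern_fits,
        stability=stability,
        prognostic=prognostic,
    )
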