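# regtriplets

Inference of **core regulatory triplets** — one long noncoding RNA
(lncRNA), one immune gene, and one stemness signature gene (SSG) — from
bulk expression cohorts, for computational biologists studying how
lncRNAs couple cancer-stemness programs to the tumor immune
microenvironment.

Given a genes × samples log2(TPM+1) matrix with gene-class labels and
per-sample metadata (tumor/normal condition, tumor purity, survival), the
package runs a staged pipeline:

1. **Screen** — Welch-*t* differential expression (|log2FC| > 1, BH
   FDR < 0.05); random walk with restart on a protein-interaction network
   to nominate SSGs near seed stemness factors
   (`p(t+1) = (1−r)·A·p(t) + r·p(0)`, restart `r = 0.85`, column-stochastic
   `A`, top 5% by influence); personalized PageRank on the tumor
   co-expression network, seeded at the SSGs, to prioritize the top-200
   lncRNAs and immune genes.
2. **Triplet scoring** — for each prioritized (lncRNA, SSG) pair, the
   weighted partial-correlation score over immune genes

   `WPC = Σᵢ βᵢ (−log₁₀(Pᵢ⁽¹⁾)·sign(corᵢ⁽¹⁾) − log₁₀(Pᵢ⁽²⁾)·sign(corᵢ⁽²⁾))`,

   where `corᵢ⁽¹⁾, Pᵢ⁽¹⁾` (resp. `⁽²⁾`) are the tumor-purity-adjusted
   partial correlation of immune gene *i* with the lncRNA (resp. the SSG),
   `PCC = (R_xy − R_xp·R_yp)/√((1−R_xp²)(1−R_yp²))`, and `βᵢ` is the
   enrichment score of the most significant immune pathway containing
   gene *i* (weighted Kolmogorov–Smirnov running sum, gene-permutation
   p < 0.05). Significance comes from an empirical null that permutes the
   lncRNA's sample labels (`p = N/n_perm`), followed by Benjamini–Hochberg
   FDR across pairs (retain FDR < 0.05).
3. **Causal pattern** — each retained triplet is assigned one of four
   regulatory patterns by BIC model selection over linear-Gaussian
   factorizations: IR `P(L)P(S|L)P(I|L)`, CR `P(L)P(I)P(S|L,I)`,
   LIS `P(L)P(I|L)P(S|I)`, LSI `P(L)P(S|L)P(I|S)`, with
   `BIC = k·ln(n) − 2·ln(L)`, `Δᵢ = BICᵢ − BIC_min`, and weights
   `ωᵢ = e^(−Δᵢ/2)/Σⱼ e^(−Δⱼ/2)`.
4. **Stability** — bootstrap mutual-information stability after
   discretizing expression into five equiprobable bins:
   `S_pair = (1/B)Σ_b [I_b(X;Z) > θ]` and
   `S_triplet = (1/B)Σ_b [I_b(X;Z|Y) > θ]` with `B = 200`, `θ = 0.2` nats;
   `ΔS = S_triplet − S_pair` measures whether the immune gene strengthens
   the lncRNA–SSG dependence.
5. **Clinical** — per-sample triplet score
   `coef_lnc·exp_lnc + coef_imm·exp_imm + coef_ssg·exp_ssg` from a
   multivariate Cox fit, patient stratification at the maximally selected
   log-rank cutoff, a dual univariate-Cox/log-rank prognostic screen,
   breadth classification of lncRNAs across cancer types (common > 10,
   specific ≤ 2), and hypergeometric set-overlap tests.

A synthetic-cohort generator (`regtriplets.synth`) plants triplets under
each causal pattern with a shared purity confounder, null background
genes, and exponential survival, so the whole pipeline is testable
without external downloads.

## Worked example

Pattern selection on planted triplets (`examples/04_select_pattern.py`):

```
true IR  -> selected IR   (omega: IR=1.00, CR=0.00, LIS=0.00, LSI=0.00)
true CR  -> selected CR   (omega: IR=0.00, CR=1.00, LIS=0.00, LSI=0.00)
true LIS -> selected LIS  (omega: IR=0.00, CR=0.00, LIS=1.00, LSI=0.00)
true LSI -> selected LSI  (omega: IR=0.00, CR=0.00, LIS=0.00, LSI=1.00)
```

At n = 500 and noise SD 0.5 every generative pattern is recovered and the
winning model carries essentially all of the BIC weight — the four DAGs
are mutually distinguishable (different skeletons, or a collider
v-structure).

Triplet scoring (`examples/03_score_triplets.py`) on a cohort with one
planted chain triplet among 30 null genes prints, for the planted pair:

```
lnc_0 - ssg_0: WPC = 217.9, permutation p = 0.0, FDR = 0,
               immune partners = ['imm_0', 'imm_0_m1', 'imm_0_m2']
```

The planted pair's WPC (≈218) dwarfs the decoy pairs (≈85–90, driven by
one-sided lncRNA evidence only), and its permutation p of 0.0 means no
null permutation out of 200 reached the observed score.

Bootstrap stability (`examples/05_bootstrap_stability.py`, B = 200,
θ = 0.2, n = 300):

```
CR : S_pair = 0.58  S_triplet = 1.00  Delta S = +0.42
LIS: S_pair = 0.07  S_triplet = 0.81  Delta S = +0.74
IR : S_pair = 0.98  S_triplet = 1.00  Delta S = +0.02
LSI: S_pair = 0.98  S_triplet = 1.00  Delta S = +0.02
```

Triplets are more stable than bare lncRNA–SSG pairs under every
generative structure at this sample size (see `docs/methods.md` for why
the plug-in estimator behaves this way).

The other examples cover cohort simulation, candidate screening, and the
clinical score; each is a short narrative script that prints what it
computes. A thin CLI mirrors the stages
(`regtriplets simulate|screen|triplets|patterns|stability|score --help`).

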