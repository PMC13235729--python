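# Methods

## Model and pipeline

The package infers lncRNA–immune-gene–SSG core regulatory triplets from a
genes × samples expression matrix on the log2(TPM+1) scale. The matrix is
assumed already harmonized across sources (batch correction is out of
scope and must happen upstream); genes with zero expression in strictly
more than 70% of samples are dropped. Gene identifiers are opaque
strings; no symbol/accession mapping is attempted.

### Network propagation

Both propagation stages use the same operator. For a weighted undirected
graph, the transition matrix `A` normalizes each node's outgoing weight
to one (column-stochastic, i.e. the out-degree-normalized random-walk
operator; symmetric normalization is not used because the iteration is a
random walk). Isolated nodes get an identity self-transition column so
`A` stays stochastic and no probability mass leaks. The fixed point of
`p(t+1) = (1−r)·A·p(t) + r·p(0)` is found by power iteration to an L1
residual below 1e-10 (closed form `r(I − (1−r)A)⁻¹p(0)`; the oracle
tests check agreement to 1e-8). Restart mass `p(0)` is uniform over the
seed set. SSG nomination uses `r = 0.85` on a protein-interaction network
(STRING-style edges kept at combined score > 700, rescaled by 1000 into
[0, 1] — the rescaling is a monotone convention and does not change the
normalized operator) and takes the top 5% of nodes by converged score,
excluding the seeds by default (a flag includes them). lncRNA/immune
prioritization is personalized PageRank with damping 0.85 on the
co-expression network, which is the same fixed point at restart
`r = 1 − damping`; the top 200 per class are kept. Ties at any top-k
cutoff are broken lexicographically by gene id for determinism.

### Differential expression and co-expression

Group comparison uses Welch's two-sample t per gene with
Benjamini–Hochberg adjustment; a gene passes when |log2FC| > 1 and
FDR < 0.05. (A moderated-t would shrink per-gene variances; at the cohort
sizes this screen targets the difference is immaterial to the downstream
stages, which never reuse the DE statistics.) The co-expression network
is built among passing lncRNA/immune/SSG genes **within tumor samples
only** — pooling tumor and normal samples would let the tumor/normal mean
shift correlate every DE gene with every other and swamp the regulatory
signal. Edge criteria (|Pearson r| ≥ 0.3 and BH-adjusted correlation-test
p < 0.05) are conventional screening values exposed as configuration;
edge weight is |r| with the sign kept as an edge attribute.

### Purity-adjusted WPC scoring

The first-order partial correlation controlling for tumor purity is
computed by the textbook formula
`(R_xy − R_xp·R_yp)/√((1−R_xp²)(1−R_yp²))`, with the two-sided p-value
from `t = pcc·√((n−3)/(1−pcc²))` on n−3 degrees of freedom. Partial
correlations, pattern fits and stability are all computed on tumor
samples only, since purity is a tumor-sample covariate.

Immune-gene weights βᵢ come from pathway enrichment specific to each
(lncRNA, SSG) pair: immune genes are ranked by the mean of their two
absolute purity-adjusted partial correlations (with the lncRNA and with
the SSG) — this pair-specific ranking metric is the design choice that
makes βᵢ differ across pairs — and each pathway's enrichment score is
the extremum of the weighted Kolmogorov–Smirnov running sum (weight
exponent 1) with a sign-matched gene-label permutation p. βᵢ is the ES of
the single most significant enriched pathway (p < 0.05) containing gene
*i* (taking one pathway rather than a sum avoids double counting genes in
overlapping pathways); genes in no enriched pathway get βᵢ = 0.

The WPC score sums the signed −log₁₀ partial-correlation evidence over
immune genes weighted by βᵢ. Exact-zero p-values are floored at
`p_floor = 1/(10·n_perm)` to keep the score finite; the same floor is
applied inside the permutation null so observed and null scores are on
the same scale. The null permutes the lncRNA's sample labels only —
this breaks the lncRNA–SSG and lncRNA–immune dependencies while
preserving the SSG/immune/purity alignment (permuting all labels jointly
would break nothing). Because WPC is signed, exceedance is two-sided:
`p = N/n_perm` with `N = #{|WPC_null| ≥ |WPC_obs|}`, kept verbatim
without a +1 pseudocount, so p = 0 is possible and is reported as
"< 1/n_perm" in the table output. BH adjustment runs across all scored
pairs and pairs with FDR < 0.05 are retained.

One structural consequence worth knowing: WPC contains only immune-gene
terms, so a pair whose lncRNA is upstream of the immune module (IR, LIS,
LSI structures) has strong lncRNA-side evidence that the permutation
destroys — high power. A pure collider pair (CR: lncRNA and immune gene
independent co-parents of the SSG) has genuinely exchangeable lncRNA
evidence under this null and is retained only at the false-positive rate.
The end-to-end expectation on a four-pattern cohort is therefore 3 of 4
planted pairs, with CR the principled miss. Symmetrically, a strong
lncRNA→immune link alone (with an unrelated SSG) can carry a pair past
the FDR threshold; the method flags lncRNA-immune-coupled pairs, not
exclusively three-way-coupled ones.

### Causal pattern selection

Each candidate triplet (L = lncRNA, S = SSG, I = immune gene) is scored
under four factorizations — IR `P(L)P(S|L)P(I|L)`, CR `P(L)P(I)P(S|L,I)`,
LIS `P(L)P(I|L)P(S|I)`, LSI `P(L)P(S|L)P(I|S)` — with each factor a
linear-Gaussian conditional at its MLE (marginal: 2 parameters;
one-parent conditional: 3; two-parent: 4; every pattern totals k = 8).
The likelihood family is linear-Gaussian because expression enters on the
continuous log scale; discretization is introduced only later for the
information-theoretic stage. Since all four k are equal, the BIC ranking
`k·ln(n) − 2·ln(L)` reduces to a likelihood ranking, but Δ and the BIC
weights ω are still reported on the BIC scale as defined. Ties select in
the fixed order IR < CR < LIS < LSI. The four DAGs are mutually
distinguishable (IR/LIS/LSI differ in skeleton; CR shares LSI's skeleton
but has a v-structure), and recovery on planted triplets at n = 300,
a = b = 0.8, noise SD 1 exceeds 80% per pattern (measured ~100%). A
degenerate factor (zero residual variance, e.g. exact collinearity) is an
error, detected at a relative threshold of 1e-13.

### Bootstrap MI/CMI stability

Expression vectors are discretized into five equiprobable quantile bins
(ties go to the lower bin; a constant vector is an error because no
equiprobable partition exists). MI and CMI are plug-in estimates in nats
from the empirical contingency tables (`I(X;Z|Y)` via the entropy
identity `H(X,Y)+H(Y,Z)−H(Y)−H(X,Y,Z)`); counts are summed in sorted
order so MI(x,z) = MI(z,x) exactly. MI is capped by ln K and this bound
is asserted on every replicate. Within each of B bootstrap replicates the
resampled vectors are re-discretized so equiprobability holds per
replicate; replicates with a constant resampled column are redrawn and
logged. Defaults are B = 200, θ = 0.2 (unitless, interpreted in nats —
the natural-log convention is configurable in the sense that a user can
rescale θ), five bins. X/Y/Z roles are fixed as
lncRNA/immune-gene/SSG.

The plug-in estimator is deliberately uncorrected (a Miller–Madow flag
is available). Its bias matters quantitatively: under bootstrap
resampling the expected number of distinct samples is ≈ 0.63·n, so the
null CMI bias is roughly `K_y(K_x−1)(K_z−1)/(2·0.63·n)` ≈ 0.21 nats at
n = 300 — above θ. Consequently S_triplet is pushed up for every
structure at moderate n, and ΔS > 0 is observed for all four generative
patterns (largest for the collider, where conditioning on the co-parent
genuinely sharpens the dependence). Triplets measuring as more stable
than pairs across the board is therefore partly an estimator property,
not purely a biological one; at the same settings the *point* estimates
(no bootstrap, larger n) do show the theoretically expected ordering,
e.g. CMI < MI for chain triplets at n = 4000. The Miller–Madow
correction shrinks but does not eliminate the bootstrap inflation
(first-order corrections under-correct in the presence of resampling
duplicates).

### Clinical utilities

The triplet score is the linear combination of the three genes'
expression with multivariate Cox coefficients (lifelines handles the
partial-likelihood numerics; the package's contribution is the score
construction and the stratification contract). The optimal cutoff scans
every admissible split between the 10% and 90% score quantiles
(min_group_fraction = 0.1, the survminer convention) and maximizes the
two-group log-rank statistic; the reported p is the naive log-rank p of
the selected split, which inherits the usual maximally-selected-statistic
inflation (a permutation-adjusted p is a documented extension, not the
default). The prognostic screen summarizes a triplet by the mean of its
three standardized expression vectors — an *unfitted* score, so the dual
criterion (univariate Cox p < 0.05 AND median-split log-rank p < 0.05)
stays calibrated under the null; using the Cox-fitted score in its own
significance test would be circular. Breadth classification labels a
lncRNA common when seen in more than 10 cancer types, specific at ≤ 2,
and intermediate for 3–10 (a label for the range the thresholds leave
unnamed); a (lncRNA, SSG) pair is pattern-variable when present in > 10
cancer types with ≥ 2 distinct selected patterns. Set-overlap
significance is the hypergeometric upper tail.

## Synthetic cohorts: what they emulate and what they do not

The generator produces linear-Gaussian structural-equation triplets —
the minimal generative family consistent with the Gaussian likelihood
used for pattern selection. L is standard normal plus `c·purity`
(purity ~ Beta(5, 2)); S and I follow the pattern's equations with
i.i.d. N(0, noise_sd²) innovations; for CR, I is an independent normal
plus `c·purity`. Purity enters additively so the partial-correlation
stage has a real confounder to remove. Null genes are i.i.d. normal,
classed round-robin. A matched normal block shifts all gene means down
by `de_shift` (default 1.5 log2 units) so every gene passes the DE
screen by construction and synthetic tests exercise the network stages
rather than the DE filter. Survival times are exponential with
log-hazard linear in a triplet score, with independent uniform
censoring.

Each planted triplet can carry an immune *module*: `n_immune − 1` noisy
copies of the canonical immune gene (copy SD 0.5). This mirrors the
set-level structure that pathway enrichment requires — enrichment is
statistically incapable of flagging a single co-regulated gene in a
small universe (the gene-permutation p is bounded below by roughly
module-size/universe-size), and real pairs in this problem domain are
reported with tens of co-regulated immune genes. The default is
n_immune = 1 (a bare triplet); the end-to-end test bed uses n_immune = 3
as its scaled-down study condition, with one synthetic pathway per
module plus decoy pathways over the null immune genes.

All randomness flows through `numpy.random.default_rng`; each triplet,
the null block, purity, the normal block and survival draw from distinct
seed-offset sub-streams, so adding a triplet to a config does not
perturb earlier genes, and a fixed seed gives bit-identical output.

What the generator does **not** emulate: negative-binomial count noise,
library-size effects, batch structure, correlated null backbones, or
non-linear/threshold regulation. Passing tests therefore demonstrate
correctness of the statistical machinery under the model's own
assumptions, not robustness to real RNA-seq artifacts.

## Problem sizes and numerical choices

Test-bed sizes are chosen for desk-scale reproduction: pattern recovery
uses 200 triplets per pattern at n = 300; null calibration 200 pairs at
n = 150 with 200 permutations; stability directionality 100 triplets per
structure at B = 50; the end-to-end cohort has 4 planted triplets
(n_immune = 3) + 50 null genes at n = 300 with n_perm = 200 and B = 50.
Degenerate inputs are errors, not silent results: constant vectors in
correlation or discretization, zero residual variance in pattern fits,
|r| = 1 with the purity covariate, seeds missing from a network. The
permutation p keeps the printed `N/n_perm` form (no pseudocount), so BH
receives exact zeros when the observed score exceeds every null draw.

## Known limitations

- The lncRNA-permutation null has no power for pure collider (CR)
  structures and flags pairs on lncRNA–immune evidence alone (see WPC
  section); interpretation of retained pairs should lean on the pattern
  and stability stages.
- Single-covariate purity adjustment only, per the first-order partial
  correlation formula; multi-covariate adjustment is out of scope.
- Bootstrap stability probabilities at moderate n are dominated by
  plug-in bias (quantified above); they are comparative diagnostics, not
  calibrated probabilities.
- The maximally selected cutoff's log-rank p is anti-conservative by
  construction.
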