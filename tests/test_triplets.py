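import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regtriplets.io import ExpressionCohort, GeneSetCollection
from regtriplets.synth import (
    SyntheticCohortConfig,
    TripletSpec,
    generate_cohort,
    generate_null_cohort,
    immune_pathway_collection,
)
from regtriplets.triplets import (
    EnrichmentWeights,
    WpcTerm,
    _running_sum_es,
    assemble_triplets,
    bh_adjust,
    compute_wpc,
    enrichment_weights,
    partial_correlation,
    permutation_test,
    wpc_score,
)


def _residual_pcor(x, y, z):
    """Independent oracle: Pearson correlation of OLS residuals on z."""
    zx = np.polyfit(z, x, 1)
    zy = np.polyfit(z, y, 1)
    rx = x - np.polyval(zx, z)
    ry = y - np.polyval(zy, z)
    return np.corrcoef(rx, ry)[0, 1]


class TestPartialCorrelation:
    def test_identical_vectors_give_one(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        assert partial_correlation(x, x, z).pcc == pytest.approx(1.0)

    def test_reduces_to_pearson_when_covariate_orthogonal(self):
        # x and y constructed exactly orthogonal to z
        z = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        y = np.array([2.0, 2.0, 1.0, 1.0, 4.0, 4.0])
        pc = partial_correlation(x, y, z)
        assert pc.r_xp == pytest.approx(0.0, abs=1e-12)
        assert pc.r_yp == pytest.approx(0.0, abs=1e-12)
        assert pc.pcc == pytest.approx(pc.r_xy)

    def test_matches_residual_regression_oracle(self):
        max_dev = 0.0
        for s in range(100):
            rng = np.random.default_rng(5000 + s)
            z = rng.normal(size=50)
            x = 0.5 * z + rng.normal(size=50)
            y = -0.3 * z + rng.normal(size=50)
            pc = partial_correlation(x, y, z)
            max_dev = max(max_dev, abs(pc.pcc - _residual_pcor(x, y, z)))
        assert max_dev < 1e-10

    def test_pvalue_matches_t_distribution(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        z = rng.normal(size=40)
        pc = partial_correlation(x, y, z)
        t = pc.pcc * np.sqrt((40 - 3) / (1 - pc.pcc**2))
        assert pc.p == pytest.approx(2 * stats.t.sf(abs(t), df=37))

    def test_constant_covariate_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(x, x + 1, np.ones(10))

    def test_degenerate_covariate_correlation_rejected(self, rng):
        z = rng.normal(size=20)
        with pytest.raises(ValueError, match="degenerate|constant"):
            partial_correlation(2 * z + 3, rng.normal(size=20), z)


class TestRunningSumEnrichment:
    def test_top_half_pathway_matches_hand_enumeration(self):
        # 10 genes, pathway = top-ranked half, weights descending
        weights = np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        membership = np.array([True] * 5 + [False] * 5)
        # brute-force running sum
        hit_norm = weights[:5].sum()
        rs, best = 0.0, 0.0
        for i in range(10):
            rs += weights[i] / hit_norm if membership[i] else -1.0 / 5
            if abs(rs) > abs(best):
                best = rs
        es = _running_sum_es(membership, weights)[0]
        assert es == pytest.approx(best)
        assert es > 0

    def test_bottom_half_pathway_negative(self):
        weights = np.linspace(1.0, 0.1, 10)
        membership = np.array([False] * 5 + [True] * 5)
        assert _running_sum_es(membership, weights)[0] < 0

    def test_planted_module_gets_nonzero_beta(self):
        specs = [TripletSpec("LIS", a=1.0, b=1.0, noise_sd=0.8, n_immune=3)]
        cfg = SyntheticCohortConfig(n_samples=200, triplet_specs=specs,
                                    n_null_genes=30, seed=31, with_normal_block=False)
        cohort, prov = generate_cohort(cfg)
        paths = immune_pathway_collection(cohort, prov, seed=31)
        w = enrichment_weights(cohort, ("lnc_0", "ssg_0"), paths,
                               n_gsea_perm=200, seed=1)
        module = set(prov.loc[prov["role"] == "immune", "gene"])
        assert all(w.beta[g] != 0 for g in module)
        assert all(w.beta[g] == 0 for g in w.beta if g not in module)

    def test_gene_outside_all_pathways_zero_beta(self, rng):
        values = pd.DataFrame(rng.normal(size=(6, 50)),
                              index=["lnc", "ssg", "i1", "i2", "i3", "i4"],
                              columns=[f"s{i}" for i in range(50)])
        cohort = ExpressionCohort(
            values,
            pd.Series({"lnc": "lncRNA", "ssg": "SSG", "i1": "immune",
                       "i2": "immune", "i3": "immune", "i4": "immune"}),
            purity=pd.Series(rng.beta(5, 2, 50), index=values.columns),
        )
        paths = GeneSetCollection({"pw": {"i1", "i2"}})
        w = enrichment_weights(cohort, ("lnc", "ssg"), paths, n_gsea_perm=100, seed=2)
        assert w.beta["i3"] == 0.0 and w.beta["i4"] == 0.0


class TestWpcScore:
    def test_empty_terms_zero(self):
        assert wpc_score([]) == 0.0

    def test_single_gene_symmetric_evidence(self):
        term = WpcTerm("g", beta=1.0, p1=0.1, cor1=0.5, p2=0.1, cor2=0.5)
        assert wpc_score([term]) == pytest.approx(2.0)

    def test_sign_cancellation(self):
        term = WpcTerm("g", beta=1.0, p1=0.01, cor1=0.5, p2=0.01, cor2=-0.5)
        assert wpc_score([term]) == pytest.approx(0.0)

    def test_additive_over_genes(self):
        t1 = WpcTerm("a", 0.7, 0.05, 0.3, 0.2, 0.4)
        t2 = WpcTerm("b", -0.2, 0.01, -0.1, 0.5, 0.9)
        assert wpc_score([t1, t2]) == pytest.approx(wpc_score([t1]) + wpc_score([t2]))

    def test_odd_under_simultaneous_sign_flip(self):
        terms = [WpcTerm("a", 0.7, 0.05, 0.3, 0.2, 0.4),
                 WpcTerm("b", 0.4, 0.01, -0.1, 0.5, 0.9)]
        flipped = [WpcTerm(t.gene, t.beta, t.p1, -t.cor1, t.p2, -t.cor2) for t in terms]
        assert wpc_score(flipped) == pytest.approx(-wpc_score(terms))

    def test_zero_pvalue_floored_with_warning(self):
        term = WpcTerm("g", 1.0, 0.0, 1.0, 0.1, 1.0)
        with pytest.warns(UserWarning, match="floor"):
            score = wpc_score([term], p_floor=1e-4)
        assert score == pytest.approx(4.0 + 1.0)


class TestBhAdjust:
    @staticmethod
    def _brute_force_bh(p):
        """Step-up BH by direct enumeration."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running_min = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running_min = min(running_min, p[i] * m / rank)
            adj[i] = running_min
        return np.clip(adj, 0, 1)

    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equally_spaced_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_on_random_inputs(self):
        for s in range(20):
            p = np.random.default_rng(s).uniform(size=15)
            np.testing.assert_allclose(bh_adjust(p), self._brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=30)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _null_pair_cohort(seed, n=150, n_immune=8):
    cohort = generate_null_cohort(2 + n_immune, n, seed=seed)
    genes = cohort.gene_ids
    mapping = {genes[0]: "lncRNA", genes[1]: "SSG"}
    for g in genes[2:]:
        mapping[g] = "immune"
    return ExpressionCohort(cohort.values, pd.Series(mapping), purity=cohort.purity)


class TestPermutationTest:
    def test_p_is_exceedance_fraction_of_returned_null(self):
        cohort = _null_pair_cohort(seed=3)
        imms = cohort.genes_of_class("immune")
        weights = EnrichmentWeights(beta={g: 1.0 for g in imms}, pathway_es={})
        pair = (cohort.genes_of_class("lncRNA")[0], cohort.genes_of_class("SSG")[0])
        p, null_scores = permutation_test(cohort, pair, weights, n_perm=100, seed=9)
        observed, _ = compute_wpc(cohort, pair, weights)
        assert null_scores.shape == (100,)
        assert p == pytest.approx(np.mean(np.abs(null_scores) >= abs(observed)))
        assert round(p * 100) == pytest.approx(p * 100)  # multiple of 1/n_perm

    def test_strong_signal_gives_zero_p(self):
        specs = [TripletSpec("LIS", a=1.2, b=1.2, noise_sd=0.4, n_immune=3)]
        cfg = SyntheticCohortConfig(n_samples=250, triplet_specs=specs,
                                    n_null_genes=12, seed=41, with_normal_block=False)
        cohort, prov = generate_cohort(cfg)
        module = sorted(prov.loc[prov["role"] == "immune", "gene"])
        weights = EnrichmentWeights(beta={g: 1.0 for g in module}, pathway_es={})
        p, _ = permutation_test(cohort, ("lnc_0", "ssg_0"), weights,
                                n_perm=200, seed=5)
        assert p == 0.0

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for s in range(60):
            cohort = _null_pair_cohort(seed=7000 + s, n=120, n_immune=5)
            imms = cohort.genes_of_class("immune")
            weights = EnrichmentWeights(beta={g: 1.0 for g in imms}, pathway_es={})
            pair = (cohort.genes_of_class("lncRNA")[0], cohort.genes_of_class("SSG")[0])
            p, _ = permutation_test(cohort, pair, weights, n_perm=100, seed=s)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_all_zero_weights_give_p_one(self):
        cohort = _null_pair_cohort(seed=13)
        weights = EnrichmentWeights(beta={g: 0.0 for g in cohort.genes_of_class("immune")},
                                    pathway_es={})
        pair = (cohort.genes_of_class("lncRNA")[0], cohort.genes_of_class("SSG")[0])
        p, null = permutation_test(cohort, pair, weights, n_perm=100, seed=1)
        assert p == 1.0


class TestAssembleTriplets:
    def test_planted_chain_pair_retained(self):
        specs = [TripletSpec("LIS", a=0.8, b=0.8, noise_sd=1.0, n_immune=3)]
        cfg = SyntheticCohortConfig(n_samples=300, triplet_specs=specs,
                                    n_null_genes=30, seed=51, with_normal_block=False)
        cohort, prov = generate_cohort(cfg)
        paths = immune_pathway_collection(cohort, prov, seed=51)
        lncs = cohort.genes_of_class("lncRNA")
        ssgs = cohort.genes_of_class("SSG")
        cands = assemble_triplets(cohort, lncs, ssgs, paths,
                                  n_perm=200, n_gsea_perm=200, seed=2)
        pairs = {(c.lncRNA, c.ssg) for c in cands}
        assert ("lnc_0", "ssg_0") in pairs
        hit = next(c for c in cands if (c.lncRNA, c.ssg) == ("lnc_0", "ssg_0"))
        assert set(hit.immune_genes) == {"imm_0", "imm_0_m1", "imm_0_m2"}
        assert hit.fdr < 0.05

    def test_wpc_consistent_with_terms(self):
        specs = [TripletSpec("IR", a=0.9, b=0.9, noise_sd=0.8, n_immune=2)]
        cfg = SyntheticCohortConfig(n_samples=200, triplet_specs=specs,
                                    n_null_genes=15, seed=61, with_normal_block=False)
        cohort, prov = generate_cohort(cfg)
        paths = immune_pathway_collection(cohort, prov, seed=61)
        cands = assemble_triplets(cohort, ["lnc_0"], ["ssg_0"], paths,
                                  n_perm=200, n_gsea_perm=200, seed=3,
                                  fdr_threshold=1.1)
        for c in cands:
            assert c.wpc == pytest.approx(wpc_score(c.per_gene_terms), abs=1e-9)

    def test_null_cohort_retention_controlled(self):
        cohort = generate_null_cohort(36, 150, seed=71)
        lncs = cohort.genes_of_class("lncRNA")[:4]
        ssgs = cohort.genes_of_class("SSG")[:5]
        imms = cohort.genes_of_class("immune")
        paths = GeneSetCollection({f"pw{j}": set(imms[j::4]) for j in range(4)})
        cands = assemble_triplets(cohort, lncs, ssgs, paths,
                                  n_perm=100, n_gsea_perm=100, seed=4)
        assert len(cands) <= 2  # of 20 null pairs

    def test_deterministic_under_fixed_seed(self):
        cohort = generate_null_cohort(15, 100, seed=81)
        lncs = cohort.genes_of_class("lncRNA")[:2]
        ssgs = cohort.genes_of_class("SSG")[:2]
        imms = cohort.genes_of_class("immune")
        paths = GeneSetCollection({"pw": set(imms)})
        runs = [
            assemble_triplets(cohort, lncs, ssgs, paths, n_perm=100,
                              n_gsea_perm=100, seed=5, fdr_threshold=1.1)
            for _ in range(2)
        ]
        for c1, c2 in zip(*runs):
            assert (c1.lncRNA, c1.ssg, c1.wpc, c1.perm_p, c1.fdr) == (
                c2.lncRNA, c2.ssg, c2.wpc, c2.perm_p, c2.fdr
            )
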