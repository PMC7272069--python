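"""Context classification and the comparative-statistics battery."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from msdart.context_stats import (
    category_association_test,
    classify_context,
    cochran_q,
    colocalization_shuffle,
    genic_bias_fisher,
    rollup_methylated_features,
    vicinity_profile,
    wilcoxon_sign_pairwise,
    window_uniformity_test,
)
from msdart.io_formats import Feature, FeatureSet
from msdart.tagbuilder import MSDSite


def _site(ccgg, chrom="c1"):
    return MSDSite(f"{chrom}:{ccgg}", chrom, ccgg)


def _features(feats):
    return FeatureSet(feats)


GENE = Feature("c1", 1000, 3000, "+", "gene", {"id": "g1"})
EXON1 = Feature("c1", 1000, 1800, "+", "exon", {"id": "g1.e1", "parent": "g1"})
EXON2 = Feature("c1", 2200, 3000, "+", "exon", {"id": "g1.e2", "parent": "g1"})
INTRON = Feature("c1", 1800, 2200, "+", "intron", {"parent": "g1"})


class TestClassifyContext:
    def test_exonic_site(self):
        fs = _features([GENE, EXON1, EXON2, INTRON])
        (ann,) = classify_context([_site(1200)], fs)
        assert ann.category == "gene_exon"
        assert ann.gene_id == "g1"
        assert ann.nearest_gene_distance == 0

    def test_intronic_site(self):
        fs = _features([GENE, EXON1, EXON2, INTRON])
        (ann,) = classify_context([_site(1900)], fs)
        assert ann.category == "gene_intron_or_utr"

    def test_utr_takes_precedence_over_exon(self):
        utr = Feature("c1", 1000, 1100, "+", "UTR", {"id": "u", "parent": "g1"})
        fs = _features([GENE, EXON1, EXON2, utr])
        (ann,) = classify_context([_site(1050)], fs)
        assert ann.category == "gene_intron_or_utr"

    def test_te_between_genes(self):
        te = Feature("c1", 5000, 5600, "+", "TE", {"id": "te1"})
        fs = _features([GENE, te])
        (ann,) = classify_context([_site(5200)], fs)
        assert ann.category == "te_intergenic"
        assert ann.te_id == "te1"
        assert ann.nearest_te_distance == 0

    def test_overlapping_genes(self):
        g2 = Feature("c1", 2500, 4000, "-", "gene", {"id": "g2"})
        fs = _features([GENE, g2])
        (ann,) = classify_context([_site(2700)], fs)
        assert ann.category == "overlapping_genes"

    def test_te_inside_intron(self):
        te = Feature("c1", 1850, 2150, "+", "TE", {"id": "te1"})
        fs = _features([GENE, EXON1, EXON2, te])
        (ann,) = classify_context([_site(1900)], fs)
        assert ann.category == "te_in_gene"

    def test_te_straddling_gene_boundary(self):
        te = Feature("c1", 2800, 3400, "+", "TE", {"id": "te1"})
        fs = _features([GENE, EXON1, EXON2, te])
        (ann,) = classify_context([_site(2900)], fs)
        assert ann.category == "te_overlapping_gene"

    def test_intergenic_with_distance(self):
        fs = _features([GENE])
        (ann,) = classify_context([_site(3500)], fs)
        assert ann.category == "intergenic"
        assert ann.nearest_gene_distance == 500  # gap from 3000 to 3500

    def test_site_beyond_chromosome_rejected(self):
        fs = _features([GENE])
        with pytest.raises(ValueError, match="beyond"):
            classify_context([_site(990)], fs, chrom_lengths={"c1": 500})

    def test_categories_partition_sites(self):
        rng = np.random.default_rng(60)
        te = Feature("c1", 5000, 5600, "+", "TE", {"id": "te1"})
        fs = _features([GENE, EXON1, EXON2, te])
        sites = [_site(int(p)) for p in rng.integers(0, 9000, size=100)]
        anns = classify_context(sites, fs)
        assert len(anns) == len(sites)  # exactly one category each


class TestVicinityProfile:
    def test_binning(self):
        from msdart.context_stats import ContextAnnotation

        anns = [
            ContextAnnotation("s1", "intergenic", 500, 20_000),
            ContextAnnotation("s2", "intergenic", 10_400, 20_000),  # excluded
            ContextAnnotation("s3", "gene_exon", 0, 20_000),  # wrong category
        ]
        obs, res = vicinity_profile(anns, background_distances=list(range(1, 10_001, 7)))
        assert obs.sum() == 1
        assert obs[0] == 1  # 500 bp falls in the first bin

    def test_calibration_under_background_proportions(self):
        from msdart.context_stats import ContextAnnotation

        rng = np.random.default_rng(61)
        bg = rng.integers(1, 10_001, size=5000)
        rejections = 0
        for rep in range(200):
            dists = rng.choice(bg, size=120)
            anns = [
                ContextAnnotation(f"s{i}", "intergenic", int(d), 0)
                for i, d in enumerate(dists)
            ]
            _, res = vicinity_profile(anns, background_distances=bg)
            rejections += res.p_value < 0.05
        assert rejections / 200 < 0.12  # close to the nominal 5% rate


class TestGenicBiasFisher:
    def test_no_bias(self):
        res = genic_bias_fisher(50, 100, 50, 100)
        assert res.p_value > 0.5

    def test_strong_bias(self):
        res = genic_bias_fisher(90, 100, 10, 100)
        assert res.p_value < 1e-10

    def test_zero_sampled_degenerate(self):
        res = genic_bias_fisher(0, 100, 0, 100)
        assert res.p_value == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            genic_bias_fisher(101, 100, 0, 100)

    def test_matches_hypergeometric_summation_oracle(self):
        rng = np.random.default_rng(62)
        for _ in range(50):
            ng, ni = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            sg = int(rng.integers(0, ng + 1))
            si = int(rng.integers(0, ni + 1))
            res = genic_bias_fisher(sg, ng, si, ni)
            # P(X >= sg) for X ~ Hypergeom(N=ng+ni, K=ng, n=sg+si)
            oracle = hypergeom.sf(sg - 1, ng + ni, ng, sg + si)
            assert res.p_value == pytest.approx(float(oracle), rel=1e-9)


class TestWindowUniformity:
    def test_uniform_sites_calibrated(self):
        rng = np.random.default_rng(63)
        rejections = 0
        for rep in range(200):
            pos = rng.integers(0, 1_000_000, size=300)
            res = window_uniformity_test({"c1": pos}, {"c1": 1_000_000}, 100_000)
            rejections += res.p_value < 0.05
        assert abs(rejections / 200 - 0.05) < 0.07

    def test_concentrated_sites_rejected(self):
        pos = np.full(200, 50)
        res = window_uniformity_test({"c1": pos}, {"c1": 1_000_000}, 100_000)
        assert res.p_value < 1e-10

    def test_single_window_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            window_uniformity_test({"c1": [5]}, {"c1": 1000}, 10_000)


class TestColocalization:
    def test_queries_equal_references(self):
        refs = [("c1", i * 1000, i * 1000 + 100) for i in range(20)]
        res = colocalization_shuffle(refs, refs, {"c1": 100_000},
                                     n_shuffles=200, seed=0)
        assert res.observed_bases == 2000
        assert res.p_bases <= 1 / 201 + 1e-12

    def test_no_references_on_chromosome(self):
        queries = [("c1", 10, 60)]
        refs = [("c2", 10, 60)]
        res = colocalization_shuffle(queries, refs, {"c1": 1000, "c2": 1000},
                                     n_shuffles=100, seed=0)
        assert res.observed_intersections == 0
        assert res.p_intersections > 0.9

    def test_interval_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            colocalization_shuffle([("c1", 0, 2000)], [], {"c1": 1000})

    def test_seeded_reproducibility_and_p_bounds(self):
        rng = np.random.default_rng(64)
        queries = [("c1", int(s), int(s) + 50) for s in rng.integers(0, 9000, 30)]
        refs = [("c1", int(s), int(s) + 200) for s in rng.integers(0, 9000, 10)]
        r1 = colocalization_shuffle(queries, refs, {"c1": 10_000}, 150, seed=5)
        r2 = colocalization_shuffle(queries, refs, {"c1": 10_000}, 150, seed=5)
        assert (r1.p_bases, r1.p_intersections) == (r2.p_bases, r2.p_intersections)
        for p in (r1.p_bases, r1.p_intersections):
            assert 1 / 151 <= p <= 1.0


class TestCochranQ:
    def test_identical_columns(self):
        x = np.tile([[1], [0], [1]], (1, 3))
        res = cochran_q(x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_toy_table_closed_form(self):
        # rows 110, 101, 110, 100 over 3 treatments: Q = 3.5 by hand
        x = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 0], [1, 0, 0]])
        res = cochran_q(x)
        assert res.statistic == pytest.approx(3.5)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(65)
        x = rng.integers(0, 2, size=(30, 4))
        q1 = cochran_q(x).statistic
        q2 = cochran_q(x[rng.permutation(30)]).statistic
        assert q1 == pytest.approx(q2)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            cochran_q(np.array([[0, 2], [1, 0]]))


class TestSignTest:
    def test_identical_columns_all_p_one(self):
        x = np.tile([[1], [0]], (5, 3))
        results = wilcoxon_sign_pairwise(x)
        assert all(r.p_value == 1.0 for r in results)

    def test_nine_vs_one_discordant(self):
        x = np.zeros((12, 2), dtype=int)
        x[:9, 0] = 1  # nine rows favor column 0
        x[9, 1] = 1  # one row favors column 1
        x[10:, :] = 1  # concordant rows do not count
        (res,) = wilcoxon_sign_pairwise(x)
        assert res.aux["n_discordant"] == 10
        # exact two-sided binomial: 2 * (C(10,0) + C(10,1)) / 2^10
        assert res.p_value == pytest.approx(2 * 11 / 1024)

    def test_fdr_matches_step_up_oracle(self):
        rng = np.random.default_rng(66)
        x = rng.integers(0, 2, size=(40, 5))
        results = wilcoxon_sign_pairwise(x)
        pv = np.array([r.p_value for r in results])
        m = pv.size
        order = np.argsort(pv)
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, pv[i] * m / rank)
            adj[i] = prev
        got = np.array([r.aux["fdr"] for r in results])
        assert np.allclose(got, adj)


class TestCategoryAssociation:
    def test_rank_one_table_zero_statistic(self):
        table = np.outer([10, 20, 30], [1, 2, 4])
        res = category_association_test(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.aux["residuals"], 0.0, atol=1e-9)

    def test_toy_2x2_closed_form(self):
        table = [[30, 10], [10, 30]]
        # chi2 = sum (o-e)^2/e with all e = 20 -> 4 * 100/20 = 20
        res = category_association_test(table)
        assert res.statistic == pytest.approx(20.0)

    def test_residual_antisymmetry_under_row_swap(self):
        table = np.array([[30, 10], [10, 30]])
        r1 = category_association_test(table).aux["residuals"]
        r2 = category_association_test(table[::-1]).aux["residuals"]
        assert np.allclose(r1, r2[::-1])
        assert np.allclose(r1[0], -r1[1])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            category_association_test([[0, 0], [1, 2]])


class TestRollup:
    def _annotations(self):
        from msdart.context_stats import ContextAnnotation

        return [
            ContextAnnotation("s1", "gene_exon", 0, 100, gene_id="g1"),
            ContextAnnotation("s2", "gene_exon", 0, 100, gene_id="g1"),
            ContextAnnotation("s3", "gene_intron_or_utr", 0, 100, gene_id="g2"),
            ContextAnnotation("s4", "te_intergenic", 100, 0, te_id="te1"),
        ]

    def test_gene_with_two_sites_counted_once(self):
        roll = rollup_methylated_features(
            self._annotations(), {"t1": {"s1", "s2"}}
        )
        assert roll.genes_per_tissue["t1"] == {"g1"}
        assert roll.gene_intersections[("t1",)] == 1

    def test_empty_calls_empty_sets(self):
        roll = rollup_methylated_features(self._annotations(), {"t1": set()})
        assert roll.genes_per_tissue["t1"] == set()

    def test_union_equals_pooled(self):
        per = {"t1": {"s1"}, "t2": {"s3", "s4"}}
        roll = rollup_methylated_features(self._annotations(), per)
        pooled = rollup_methylated_features(
            self._annotations(), {"all": {"s1", "s3", "s4"}}
        )
        union_genes = roll.genes_per_tissue["t1"] | roll.genes_per_tissue["t2"]
        assert union_genes == pooled.genes_per_tissue["all"]
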