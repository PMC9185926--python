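"""Loop/gene classification, promoter scores, quantile normalization, and
differential loop-regulation calling."""

import numpy as np
import pandas as pd
import pytest

from epmap.core import (ChromatinLoop, CisRegElement, Gene, GenomicInterval,
                        IntervalIndex, overlaps)
from epmap.loops import (classify_gene, classify_loop, correlate_level_changes,
                         differential_genes, enhancers_per_promoter,
                         expression_by_enhancer_count, nearest_gene_skipping,
                         promoter_interaction_score, promoter_region,
                         quantile_normalize)


def _loop(start1, start2, fdr=0.01, chrom="chr1", count=5):
    return ChromatinLoop(GenomicInterval(chrom, start1, start1 + 5000),
                         GenomicInterval(chrom, start2, start2 + 5000),
                         count, fdr)


def _cre_index(entries):
    """entries: list of (start, end, cre_class)."""
    cres = [CisRegElement(GenomicInterval("chr1", s, e), cls, f"c{i}")
            for i, (s, e, cls) in enumerate(entries)]
    return IntervalIndex(cres, key=lambda c: c.interval)


class TestClassifyLoop:
    # anchors at [0,5000) and [100000,105000); CRE content per anchor drives class
    CONTENT = {"P": "active_promoter", "E": "enhancer", "-": None}
    EXPECTED = {
        ("P", "P"): "PP", ("P", "E"): "PE", ("E", "P"): "PE", ("E", "E"): "EE",
        ("P", "-"): "P_none", ("-", "P"): "P_none",
        ("E", "-"): "E_none", ("-", "E"): "E_none", ("-", "-"): "unclear",
    }

    @pytest.mark.parametrize("a,b", list(EXPECTED))
    def test_nine_cell_truth_table(self, a, b):
        entries = []
        if self.CONTENT[a]:
            entries.append((1000, 2000, self.CONTENT[a]))
        if self.CONTENT[b]:
            entries.append((101_000, 102_000, self.CONTENT[b]))
        assert classify_loop(_loop(0, 100_000), _cre_index(entries)) == \
            self.EXPECTED[(a, b)]

    def test_super_enhancer_counts_as_enhancer(self):
        idx = _cre_index([(1000, 2000, "super_enhancer"),
                          (101_000, 102_000, "enhancer")])
        assert classify_loop(_loop(0, 100_000), idx) == "EE"

    def test_promoter_precedence_on_shared_anchor(self):
        idx = _cre_index([(1000, 2000, "active_promoter"), (2500, 3500, "enhancer"),
                          (101_000, 102_000, "enhancer")])
        assert classify_loop(_loop(0, 100_000), idx) == "PE"


class TestClassifyGene:
    GENE = Gene("g1", GenomicInterval("chr1", 1000, 9000), "+")  # TSS at 1000

    def test_no_loops_is_type_I(self):
        assert classify_gene(self.GENE, [], _cre_index([])) == "I"

    def test_enhancer_only_is_type_II(self):
        idx = _cre_index([(101_000, 102_000, "enhancer")])
        assert classify_gene(self.GENE, [_loop(0, 100_000)], idx) == "II"

    def test_promoter_only_is_type_III(self):
        idx = _cre_index([(101_000, 102_000, "active_promoter")])
        assert classify_gene(self.GENE, [_loop(0, 100_000)], idx) == "III"

    def test_both_is_type_IV(self):
        idx = _cre_index([(101_000, 102_000, "active_promoter"),
                          (201_000, 202_000, "enhancer")])
        loops = [_loop(0, 100_000), _loop(0, 200_000)]
        assert classify_gene(self.GENE, loops, idx) == "IV"

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            genes = [Gene(f"g{i}", GenomicInterval(
                "chr1", s := int(rng.integers(0, 900_000)), s + 8000), "+")
                for i in range(5)]
            cres = [CisRegElement(GenomicInterval(
                "chr1", s := int(rng.integers(0, 990_000)), s + 2000),
                ["active_promoter", "enhancer"][int(rng.integers(2))], f"c{i}")
                for i in range(15)]
            idx = IntervalIndex(cres, key=lambda c: c.interval)
            loops = []
            for _ in range(12):
                s1 = int(rng.integers(0, 800_000))
                s2 = s1 + 5000 * int(rng.integers(2, 40))
                loops.append(_loop((s1 // 5000) * 5000, (s2 // 5000) * 5000))
            for g in genes:
                prom = promoter_region(g, idx)
                has_p = has_e = False
                for lp in loops:
                    for mine, other in ((lp.anchor1, lp.anchor2),
                                        (lp.anchor2, lp.anchor1)):
                        if overlaps(mine, prom):
                            for c in cres:
                                if overlaps(c.interval, other):
                                    if c.is_promoter:
                                        has_p = True
                                    else:
                                        has_e = True
                expected = {(False, False): "I", (False, True): "II",
                            (True, False): "III", (True, True): "IV"}[(has_p, has_e)]
                assert classify_gene(g, loops, idx) == expected


class TestEnhancersPerPromoter:
    GENE = Gene("g1", GenomicInterval("chr1", 1000, 9000), "+")

    def test_no_loops(self):
        assert enhancers_per_promoter(self.GENE, [], _cre_index([])) == 0

    def test_two_loops_same_enhancer_counted_once(self):
        idx = _cre_index([(101_000, 102_000, "enhancer")])
        loops = [_loop(0, 100_000), _loop(0, 100_000, fdr=0.001)]
        assert enhancers_per_promoter(self.GENE, loops, idx) == 1

    def test_mean_matches_planted_counts(self, mini_bundle):
        b = mini_bundle
        idx = IntervalIndex(b.cres, key=lambda c: c.interval)
        union = b.loops_by_sample["lean_rep1"]
        planted = b.truth.enhancer_counts
        observed = {g.gene_id: enhancers_per_promoter(g, union, idx)
                    for g in b.genes}
        # observed counts can only exceed planted ones (background loops add links)
        for gid, n in planted.items():
            assert observed[gid] >= n
        mean_obs = np.mean([observed[g] for g in planted])
        mean_planted = np.mean(list(planted.values()))
        assert mean_obs == pytest.approx(mean_planted, abs=1.0)


class TestNearestGeneSkipping:
    GENES = [Gene("near", GenomicInterval("chr1", 50_000, 60_000), "+"),
             Gene("far", GenomicInterval("chr1", 300_000, 310_000), "+")]
    ENH = CisRegElement(GenomicInterval("chr1", 79_500, 80_500), "enhancer", "e")

    def test_target_is_nearest(self):
        assert nearest_gene_skipping(self.ENH, self.GENES[0], self.GENES) is False

    def test_target_skips_intervening_gene(self):
        assert nearest_gene_skipping(self.ENH, self.GENES[1], self.GENES) is True

    def test_cross_chromosome_raises(self):
        other = Gene("x", GenomicInterval("chr2", 0, 10_000), "+")
        with pytest.raises(ValueError):
            nearest_gene_skipping(self.ENH, other, self.GENES + [other])

    def test_bundle_fraction_near_target(self, bundle):
        genes_by_id = {g.gene_id: g for g in bundle.genes}
        cres_by_id = {c.id: c for c in bundle.cres}
        flags = [nearest_gene_skipping(cres_by_id[e["enhancer_id"]],
                                       genes_by_id[e["gene_id"]], bundle.genes)
                 for e in bundle.truth.reg_loops]
        assert np.mean(flags) == pytest.approx(0.75, abs=0.05)


class TestPromoterScore:
    GENE = Gene("g1", GenomicInterval("chr1", 1000, 9000), "+")

    def test_hand_computed_sum(self):
        loops = [_loop(0, 100_000, fdr=0.01), _loop(0, 200_000, fdr=0.1)]
        assert promoter_interaction_score(self.GENE, loops).score == pytest.approx(3.0)

    def test_no_touching_loops(self):
        loops = [_loop(500_000, 600_000, fdr=0.01)]
        assert promoter_interaction_score(self.GENE, loops).score == 0.0

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            gene = Gene("g", GenomicInterval(
                "chr1", s := int(rng.integers(0, 500_000)), s + 10_000), "+")
            prom = promoter_region(gene)
            loops = []
            for _ in range(rng.integers(1, 15)):
                s1 = 5000 * int(rng.integers(0, 100))
                s2 = s1 + 5000 * int(rng.integers(2, 30))
                loops.append(_loop(s1, s2, fdr=float(10 ** -rng.uniform(0.5, 6))))
            expected = sum(-np.log10(lp.fdr) for lp in loops
                           if overlaps(lp.anchor1, prom) or overlaps(lp.anchor2, prom))
            got = promoter_interaction_score(gene, loops).score
            assert got == pytest.approx(expected)

    def test_additive_over_disjoint_loop_sets(self):
        l1 = [_loop(0, 100_000, fdr=0.01)]
        l2 = [_loop(0, 200_000, fdr=0.001)]
        s1 = promoter_interaction_score(self.GENE, l1).score
        s2 = promoter_interaction_score(self.GENE, l2).score
        s12 = promoter_interaction_score(self.GENE, l1 + l2).score
        assert s12 == pytest.approx(s1 + s2)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        assert np.allclose(quantile_normalize(m), m)

    def test_two_column_hand_case(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_ties_receive_mean_of_target_values(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        target = np.sort(m.values, axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        assert np.allclose(out["a"], [2.0, 2.0, 5.5])  # mean(1.5, 2.5) for the tie
        assert np.allclose(out["b"], target)

    def test_random_matrices_share_multiset_and_preserve_ranks(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = pd.DataFrame(rng.normal(size=(int(rng.integers(5, 40)), 4)))
            out = quantile_normalize(m)
            ref = np.sort(out.iloc[:, 0].to_numpy())
            for j in range(4):
                assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)
                before = np.argsort(m.iloc[:, j].to_numpy(), kind="stable")
                after = np.argsort(out.iloc[:, j].to_numpy(), kind="stable")
                assert np.array_equal(before, after)

    def test_single_sample_identity_with_warning(self):
        m = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        assert np.allclose(out, m)


class TestDifferentialGenes:
    def test_equal_conditions_all_ns(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.gamma(2, 10, size=(100, 2)),
                         index=[f"g{i}" for i in range(100)])
        res = differential_genes(m, m.copy())
        assert all(r.direction == "ns" for r in res)
        assert all(r.log2fc == 0 for r in res)

    def test_single_gene_arithmetic(self):
        a = pd.DataFrame({"r1": [8.0], "r2": [8.0]}, index=["g"])
        b = pd.DataFrame({"r1": [2.0], "r2": [2.0]}, index=["g"])
        res = differential_genes(a, b, pseudocount=1.0)
        assert res[0].log2fc == pytest.approx(np.log2(9 / 3))

    def test_all_zero_gene_is_ns_with_p_one(self):
        a = pd.DataFrame({"r1": [0.0, 5.0], "r2": [0.0, 6.0]}, index=["z", "g"])
        b = pd.DataFrame({"r1": [0.0, 5.0], "r2": [0.0, 4.0]}, index=["z", "g"])
        res = differential_genes(a, b)
        z = next(r for r in res if r.gene_id == "z")
        assert (z.p_value, z.direction, z.log2fc) == (1.0, "ns", 0.0)

    def test_planted_fold_change_recovery(self):
        rng = np.random.default_rng(2)
        n, n_up = 500, 50
        base = rng.gamma(3, 20, size=n)
        def reps(mult):
            return np.column_stack([
                np.maximum(base * mult * np.exp(rng.normal(0, 0.1, n)), 0)
                for _ in range(2)])
        mult = np.ones(n)
        mult[:n_up] = 4.0
        a = pd.DataFrame(reps(mult), index=[f"g{i}" for i in range(n)])
        b = pd.DataFrame(reps(np.ones(n)), index=a.index)
        res = differential_genes(a, b, lfc_thresh=1.5)
        hits = {r.gene_id for r in res if r.direction == "up_A" and r.q_value < 0.05}
        truth = {f"g{i}" for i in range(n_up)}
        assert len(hits & truth) / n_up >= 0.9
        fp = len(hits - truth)
        assert fp <= 0.05 * max(len(hits), 1)

    def test_permuted_null_calibration(self):
        rng = np.random.default_rng(6)
        n = 500
        scores = rng.gamma(3, 20, size=(n, 8)) * np.exp(rng.normal(0, 0.2, (n, 8)))
        m = pd.DataFrame(scores, index=[f"g{i}" for i in range(n)])
        perm = rng.permutation(8)
        a, b = m.iloc[:, perm[:4]], m.iloc[:, perm[4:]]
        res = differential_genes(a, b)
        frac = np.mean([r.p_value < 0.05 for r in res])
        assert frac <= 0.07


class TestCorrelateAndExpression:
    def test_identical_vectors(self):
        r, _ = correlate_level_changes([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_negated_vector(self):
        r, _ = correlate_level_changes([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=500)
        r, p = correlate_level_changes(x, y)
        assert r == pytest.approx(0.8, abs=0.06)
        assert p < 1e-10

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlate_level_changes([1, 1, 1], [1, 2, 3])

    def test_expression_rises_with_enhancer_count(self, mini_bundle):
        slope, r, p_kw = expression_by_enhancer_count(
            mini_bundle.genes, mini_bundle.truth.enhancer_counts)
        assert slope > 0
        assert p_kw < 0.01
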