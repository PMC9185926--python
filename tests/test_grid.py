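"""Bridge-linker read parsing, mate assignment, and caRNA calling."""

import numpy as np
import pytest

from epmap.core import Gene, Genome, GenomicInterval, KmerLocator, revcomp
from epmap.grid import (ContactPair, LinkerSpec, background_correct,
                        bin_contact_counts, call_caRNAs, classify_mode,
                        classify_pairs, differential_caRNA_genes,
                        parse_grid_read, parse_reads, assign_pairs)
from epmap.simulate import default_linker

LINKER = default_linker()


def make_read(rna, dna, flip=False, linker=LINKER):
    seq = revcomp(rna) + linker.full_seq + dna
    return revcomp(seq) if flip else seq


class TestLinkerSpec:
    def test_seed_must_occur_once(self):
        with pytest.raises(ValueError):
            LinkerSpec(full_seq="ACGTACGTACGTACGTACGT" * 3, seed12="ACGTACGTACGT")

    def test_seed_must_be_12bp(self):
        with pytest.raises(ValueError):
            LinkerSpec(full_seq="A" * 40 + "CGTGCA", seed12="CGTGCA")


class TestParseGridRead:
    RNA = "ACGTTGCAACGTTGCAACGT"   # 20 bp formal RNA read
    DNA = "TTGCAACGTTGCAACGTTG"    # 19 bp

    @pytest.mark.parametrize("flip", [False, True])
    def test_exact_mate_recovery(self, flip):
        read = make_read(self.RNA, self.DNA, flip=flip)
        assert len(read) >= 79
        p = parse_grid_read(read, LINKER)
        assert p.status == "ok"
        assert p.rna_seq == self.RNA
        assert p.dna_seq == self.DNA

    def test_short_read_rejected(self):
        p = parse_grid_read("ACGT" * 17 + "AC", LINKER)  # 70 bp
        assert p.status == "min_length"

    def test_mutated_seed_rejected(self):
        read = make_read(self.RNA, self.DNA)
        i = read.index(LINKER.seed12)
        bad = read[:i + 4] + ("A" if read[i + 4] != "A" else "C") \
            + ("G" if read[i + 5] != "G" else "T") + read[i + 6:]
        p = parse_grid_read(bad, LINKER)
        assert p.status == "no_seed"

    def test_one_mismatch_tolerated_when_allowed(self):
        lenient = LinkerSpec(LINKER.full_seq, LINKER.seed12, max_seed_mismatches=1)
        read = make_read(self.RNA, self.DNA)
        i = read.index(LINKER.seed12)
        bad = read[:i + 4] + ("A" if read[i + 4] != "A" else "C") + read[i + 5:]
        assert parse_grid_read(bad, LINKER).status == "no_seed"
        assert parse_grid_read(bad, lenient).status == "ok"

    def test_two_linkers_ambiguous(self):
        read = revcomp(self.RNA) + LINKER.full_seq + LINKER.full_seq + self.DNA
        assert parse_grid_read(read, LINKER).status == "ambiguous_linker"

    def test_mate_length_out_of_range(self):
        p = parse_grid_read(make_read(self.RNA, self.DNA + "ACGTACGTAC"), LINKER)
        assert p.status == "mate_length"

    def test_truncated_linker_boundary(self):
        # seed present but linker runs off the read end
        read = revcomp(self.RNA) + revcomp(self.RNA) + revcomp(self.RNA) \
            + LINKER.full_seq[:LINKER.seed_offset + 12 + 3]
        assert len(read) >= 79
        assert parse_grid_read(read, LINKER).status == "linker_boundary"

    def test_statuses_partition_inputs(self, mini_bundle):
        from epmap.simulate import SimConfig, simulate
        cfg = mini_bundle.config
        corrupted = simulate(SimConfig(**{**cfg.__dict__, "grid_corrupt_frac": 0.3}))
        parsed, status = parse_reads(corrupted.grid_reads, LINKER)
        assert sum(status.values()) == len(corrupted.grid_reads)
        truth = corrupted.truth.read_truth
        for p in parsed:
            kind = truth[p.read_id]["corrupt"]
            if kind is None:
                assert p.status == "ok"
                assert p.rna_seq == truth[p.read_id]["rna_seq"]
                assert p.dna_seq == truth[p.read_id]["dna_seq"]
            else:
                expected = {"seed_mut": "no_seed", "truncate": "min_length",
                            "long_mate": "mate_length"}[kind]
                assert p.status == expected

    def test_full_corruption_of_seed_yields_no_ok(self, mini_bundle):
        reads = [(rid, seq.replace(LINKER.seed12, "A" * 12)
                  .replace(revcomp(LINKER.seed12), "T" * 12))
                 for rid, seq in mini_bundle.grid_reads]
        _, status = parse_reads(reads, LINKER)
        assert status.get("ok", 0) == 0


class TestAssignPairs:
    def test_nonunique_mate_dropped(self):
        rng = np.random.default_rng(0)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        dup = core[100:123]
        genome = Genome({"chr1": core + dup + core[2000:]})  # dup appears twice
        loc = KmerLocator(genome)
        unique_rna = core[3000:3020]
        from epmap.grid import ParsedRead
        parsed = [ParsedRead("r1", "ok", rna_seq=unique_rna, dna_seq=dup)]
        pairs, stats = assign_pairs(parsed, loc, [])
        assert pairs == []
        assert stats["n_nonunique"] == 1

    def test_intergenic_rna_kept_unassigned(self, mini_bundle):
        b = mini_bundle
        # a mate from far outside any gene on chr1
        gene_free = max(b.genes, key=lambda g: g.interval.start).interval.end + 50_000
        seq = b.genome.seq("chr1", gene_free, gene_free + 20)
        from epmap.grid import ParsedRead
        parsed = [ParsedRead("r1", "ok", rna_seq=seq, dna_seq=seq)]
        pairs, _ = assign_pairs(parsed, b.locator, b.genes)
        if pairs:  # unique location (overwhelmingly likely)
            assert pairs[0].source_gene is None

    def test_round_trip_recovery_on_bundle(self, mini_bundle):
        b = mini_bundle
        parsed, status = parse_reads(b.grid_reads, b.config.linker)
        pairs, stats = assign_pairs(parsed, b.locator, b.genes)
        truth = b.truth.read_truth
        assert stats["n_pairs"] / len(b.grid_reads) >= 0.999
        ok_pos = sum(
            1 for p in pairs
            if (p.rna_chrom, p.rna_pos, p.dna_chrom, p.dna_pos) ==
            (truth[p.read_id]["rna_chrom"], truth[p.read_id]["rna_pos"],
             truth[p.read_id]["dna_chrom"], truth[p.read_id]["dna_pos"]))
        assert ok_pos == len(pairs)


class TestClassifyMode:
    GENE = Gene("g1", GenomicInterval("chr1", 100_000, 120_000), "+")

    def _pair(self, chrom, pos):
        return ContactPair("r", "chr1", 105_000, "+", chrom, pos, source_gene="g1")

    @pytest.mark.parametrize("chrom,pos,expected", [
        ("chr2", 105_000, "trans"),
        ("chr1", 95_000, "local"),        # 5 kb upstream of gene start
        ("chr1", 90_000, "local"),        # exactly at the -10 kb boundary
        ("chr1", 89_999, "cis"),
        ("chr1", 129_999, "local"),       # just inside the +10 kb flank
        ("chr1", 130_000, "cis"),
        ("chr1", 170_000, "cis"),
    ])
    def test_boundaries(self, chrom, pos, expected):
        assert classify_mode(self._pair(chrom, pos), self.GENE) == expected

    def test_unassigned_gene_raises(self):
        p = ContactPair("r", "chr1", 0, "+", "chr1", 0)
        with pytest.raises(ValueError):
            classify_mode(p, self.GENE)

    def test_mode_fractions_sum_to_one(self, mini_bundle):
        carnas = call_caRNAs(mini_bundle.contacts, mini_bundle.genes)
        for c in carnas:
            assert sum(c.mode_fractions) == pytest.approx(1.0)


class TestCallCaRNAs:
    def _uniform_pairs(self, genes, n, rng):
        pairs = []
        for i in range(n):
            g = genes[int(rng.integers(len(genes)))]
            pairs.append(ContactPair(f"r{i}", g.chrom, g.interval.start, "+",
                                     g.chrom, g.interval.start, g.gene_id, "local"))
        return pairs

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(1)
        genes = [Gene(f"g{i}", GenomicInterval("chr1", 10_000 * i + 1000,
                                               10_000 * i + 9000), "+")
                 for i in range(100)]
        pairs = self._uniform_pairs(genes, 1000, rng)  # ~10 per gene
        hot = genes[0]
        pairs += [ContactPair(f"h{i}", hot.chrom, hot.interval.start, "+",
                              hot.chrom, hot.interval.start, hot.gene_id, "local")
                  for i in range(90)]  # 10x background
        res = call_caRNAs(pairs, genes)
        by_id = {c.gene_id: c for c in res}
        assert by_id["g0"].enriched

    def test_uniform_null_low_false_positive_rate(self):
        rng = np.random.default_rng(2)
        genes = [Gene(f"g{i}", GenomicInterval("chr1", 10_000 * i + 1000,
                                               10_000 * i + 9000), "+")
                 for i in range(200)]
        res = call_caRNAs(self._uniform_pairs(genes, 4000, rng), genes)
        assert np.mean([c.enriched for c in res]) <= 0.07

    def test_gene_with_no_pairs_absent(self):
        genes = [Gene("g0", GenomicInterval("chr1", 0, 1000), "+"),
                 Gene("g1", GenomicInterval("chr1", 5000, 6000), "+")]
        pairs = [ContactPair("r", "chr1", 0, "+", "chr1", 0, "g0", "local")]
        assert [c.gene_id for c in call_caRNAs(pairs, genes)] == ["g0"]


class TestBackgroundCorrect:
    def test_uniform_gives_constant(self):
        obs = {"chr1": np.full(50, 4.0)}
        bg = {"chr1": np.full(50, 2.0)}
        corr, warned = background_correct(obs, bg)
        assert not warned
        inner = corr["chr1"][5:-5]  # edges see the smoothing window shrink
        assert np.allclose(inner, inner[0])

    def test_hotspot_ratio_preserved(self):
        obs = {"chr1": np.full(50, 10.0)}
        obs["chr1"][25] = 50.0
        bg = {"chr1": np.full(50, 9.0)}
        corr, _ = background_correct(obs, bg)
        assert corr["chr1"][25] / corr["chr1"][10] == pytest.approx(5.0)

    def test_empty_background_is_identity_with_warning(self):
        obs = {"chr1": np.array([1.0, 2.0, 3.0])}
        corr, warned = background_correct(obs, {"chr1": np.zeros(3)})
        assert warned
        assert np.array_equal(corr["chr1"], obs["chr1"])

    def test_bin_counts_respect_mode_filter(self, mini_bundle):
        lens = mini_bundle.chrom_lengths
        allm = bin_contact_counts(mini_bundle.contacts, lens)
        trans = bin_contact_counts(mini_bundle.contacts, lens, mode="trans")
        assert sum(v.sum() for v in allm.values()) == len(mini_bundle.contacts)
        n_trans = sum(1 for p in mini_bundle.contacts if p.mode == "trans")
        assert sum(v.sum() for v in trans.values()) == n_trans


class TestDifferentialCaRNA:
    def test_equal_conditions_ns(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.gamma(2, 10, size=(50, 2)))
        assert all(r.direction == "ns" for r in differential_caRNA_genes(m, m.copy()))

    def test_exact_threshold_is_ns(self):
        import pandas as pd
        # log2fc == 2.0 exactly: the rule is strict inequality
        a = pd.DataFrame({"r1": [15.0], "r2": [15.0]}, index=["g"])
        b = pd.DataFrame({"r1": [3.0], "r2": [3.0]}, index=["g"])
        res = differential_caRNA_genes(a, b, pseudocount=1.0)
        assert res[0].log2fc == pytest.approx(2.0)
        assert res[0].direction == "ns"

    def test_planted_eightfold_recovered(self):
        import pandas as pd
        rng = np.random.default_rng(3)
        n, n_up = 300, 30
        base = rng.gamma(3, 30, size=n)
        mult = np.ones(n)
        mult[:n_up] = 8.0
        def reps(m):
            return np.column_stack([base * m * np.exp(rng.normal(0, 0.1, n))
                                    for _ in range(2)])
        a = pd.DataFrame(reps(mult), index=[f"g{i}" for i in range(n)])
        b = pd.DataFrame(reps(np.ones(n)), index=a.index)
        res = differential_caRNA_genes(a, b)
        hits = {r.gene_id for r in res if r.direction == "up_A" and r.q_value < 0.05}
        assert len(hits & {f"g{i}" for i in range(n_up)}) / n_up >= 0.9
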