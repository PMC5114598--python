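import numpy as np
import pytest
from scipy import stats as sps

from panpav import variation_stats as vs
from panpav.io_formats import GeneModel, PavMatrix, SnpRecord
from oracles import mann_whitney_exact, rebuild_translate_effect


def snp(pos, ref, alt, genotype="hom_alt", seq="chr1", line="L1"):
    return SnpRecord(seq, pos, ref, alt, genotype, line)


class TestRemoveHeterozygous:
    def test_filtering(self):
        kept = vs.remove_heterozygous([snp(1, "A", "G", "het"),
                                       snp(2, "C", "T", "hom_alt")])
        assert [s.pos for s in kept] == [2]

    def test_empty(self):
        assert vs.remove_heterozygous([]) == []


class TestClassifySnp:
    # plus-strand single-exon gene, CDS = AAA TGG TAA-free codons
    REF = "AAATGGCTGACG" + "T" * 8
    GENE = GeneModel("g", "chr1", "+", ((1, 12),))

    def test_synonymous_lys(self):
        # AAA -> AAG at codon position 3: Lys -> Lys
        got = vs.classify_snp(snp(3, "A", "G"), self.GENE, self.REF)
        assert (got.context, got.effect) == ("coding", "synonymous")

    def test_nonsense_trp_to_stop(self):
        # codon 2 TGG -> TGA: Trp -> stop
        got = vs.classify_snp(snp(6, "G", "A"), self.GENE, self.REF)
        assert got.effect == "nonsense"

    def test_nonsynonymous(self):
        # codon 1 AAA -> ACA: Lys -> Thr
        got = vs.classify_snp(snp(2, "A", "C"), self.GENE, self.REF)
        assert got.effect == "nonsynonymous"

    def test_non_coding_outside_exons(self):
        got = vs.classify_snp(snp(15, "T", "C"), self.GENE, self.REF)
        assert (got.context, got.effect) == ("non_coding", "none")

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            vs.classify_snp(snp(1, "C", "G"), self.GENE, self.REF)

    def test_minus_strand_against_rebuild_oracle(self):
        # minus-strand gene: genomic T->C in the codon rebuilt from revcomp
        ref = "TTACCATGGTGA"
        gene = GeneModel("g", "chr1", "-", ((1, 12),))
        for pos in range(1, 13):
            base = ref[pos - 1]
            for alt in "ACGT":
                if alt == base:
                    continue
                got = vs.classify_snp(snp(pos, base, alt), gene, ref)
                want = rebuild_translate_effect(gene.exons, "-", ref, pos, alt)
                assert (got.context, got.effect) == want

    def test_random_instances_match_oracle(self, rng):
        for _ in range(1000):
            n_ex = int(rng.integers(1, 4))
            pos, exons = int(rng.integers(1, 10)), []
            for _ in range(n_ex):
                ln = 3 * int(rng.integers(2, 8))
                exons.append((pos, pos + ln - 1))
                pos += ln + int(rng.integers(2, 12))
            seq_len = pos + 10
            ref = "".join(rng.choice(list("ACGT"), size=seq_len))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneModel("g", "chr1", strand, tuple(exons))
            p = int(rng.integers(1, seq_len + 1))
            base = ref[p - 1]
            alt = "ACGT".replace(base, "")[int(rng.integers(3))]
            got = vs.classify_snp(snp(p, base, alt), gene, ref)
            want = rebuild_translate_effect(exons, strand, ref, p, alt)
            assert (got.context, got.effect) == want, (exons, strand, p)

    def test_effect_counts_partition_coding_snps(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=300))
        gene = GeneModel("g", "chr1", "+", ((31, 90), (121, 240)))
        results = []
        for p in range(1, 301):
            base = ref[p - 1]
            results.append(vs.classify_snp(snp(p, base, "A" if base != "A"
                                               else "G"), gene, ref))
        coding = [r for r in results if r.context == "coding"]
        assert len(coding) == gene.total_exon_length
        assert all(r.effect in ("synonymous", "nonsynonymous", "nonsense")
                   for r in coding)


class TestGeneSnpStats:
    def test_density_arithmetic(self):
        gene = GeneModel("g", "chr1", "+", ((1, 999),))
        pav = PavMatrix(["g"], [f"L{i}" for i in range(10)],
                        np.ones((1, 10), int))
        snps = [snp(10 * i + 1, "A", "G") for i in range(5)]
        st = vs.gene_snp_stats(gene, snps, pav)
        assert st.coding_snp_count == 5
        assert st.presence_count == 10
        assert st.density_per_kb == pytest.approx(1000 * 5 / 999)
        assert st.normalized_density == pytest.approx(st.density_per_kb / 10)

    def test_zero_snps_zero_density(self):
        gene = GeneModel("g", "chr1", "+", ((1, 300),))
        pav = PavMatrix(["g"], ["L1", "L2"], [[1, 1]])
        st = vs.gene_snp_stats(gene, [], pav)
        assert st.density_per_kb == 0.0

    def test_presence_one_normalized_equals_raw(self):
        gene = GeneModel("g", "chr1", "+", ((1, 300),))
        pav = PavMatrix(["g"], ["L1", "L2"], [[1, 0]])
        st = vs.gene_snp_stats(gene, [snp(5, "A", "G")], pav)
        assert st.normalized_density == st.density_per_kb
        assert st.label == "variable"

    def test_gene_missing_from_pav(self):
        gene = GeneModel("x", "chr1", "+", ((1, 300),))
        pav = PavMatrix(["g"], ["L1"], [[1]])
        with pytest.raises(ValueError):
            vs.gene_snp_stats(gene, [], pav)


class TestCompareCoreVariable:
    def test_identical_samples_p_one(self):
        got = vs.compare_core_variable([1, 2, 3], [1, 2, 3])
        assert got["p"] == pytest.approx(1.0)

    def test_all_tied_p_one(self):
        got = vs.compare_core_variable([5, 5, 5], [5, 5])
        assert got["p"] == 1.0 and got["direction"] == "tied"

    def test_separated_samples_match_exhaustive_oracle(self):
        core, variable = [1, 2, 3], [4, 5, 6]
        got = vs.compare_core_variable(core, variable)
        u_exact, p_exact = mann_whitney_exact(core, variable)
        assert got["U"] == u_exact == 0.0
        assert got["direction"] == "variable_higher"
        assert abs(got["p"] - p_exact) < 0.05

    def test_u_matches_oracle_on_random_small_samples(self, rng):
        for _ in range(50):
            a = rng.integers(0, 6, size=int(rng.integers(3, 8))).tolist()
            b = rng.integers(0, 6, size=int(rng.integers(3, 8))).tolist()
            if len(set(a + b)) == 1:
                continue
            got = vs.compare_core_variable(a, b)
            u_exact, p_exact = mann_whitney_exact(a, b)
            assert got["U"] == pytest.approx(u_exact)
            assert abs(got["p"] - p_exact) < 0.12

    def test_shift_alternative_detected(self):
        detected = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = r.normal(0, 1, 500)
            b = r.normal(0.5, 1, 500)
            if vs.compare_core_variable(a, b)["p"] < 0.001:
                detected += 1
        assert detected >= 95

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            vs.compare_core_variable([], [1.0])


class TestTeWindowDensity:
    GENE = GeneModel("g", "chr1", "+", ((5001, 6000),))

    def test_no_te_zero(self):
        assert vs.te_window_density(self.GENE, [], 20000) == 0.0

    def test_full_windows_one(self):
        te = [("chr1", 3001, 5000), ("chr1", 6001, 8000)]
        assert vs.te_window_density(self.GENE, te, 20000) == 1.0

    def test_partial_upstream(self):
        # 500 TE bp upstream only over 4000 window bp -> 0.125
        te = [("chr1", 4001, 4500)]
        assert vs.te_window_density(self.GENE, te, 20000) == \
            pytest.approx(0.125)

    def test_overlapping_te_merged(self):
        te = [("chr1", 4001, 4500), ("chr1", 4201, 4500)]
        assert vs.te_window_density(self.GENE, te, 20000) == \
            pytest.approx(0.125)

    def test_truncation_at_sequence_edge(self):
        gene = GeneModel("g", "chr1", "+", ((501, 1500),))
        # upstream window truncated to 500 bp; downstream full 2000
        te = [("chr1", 1, 500)]
        assert vs.te_window_density(gene, te, 10000) == \
            pytest.approx(500 / 2500)

    def test_other_sequence_ignored(self):
        te = [("chr2", 3001, 5000)]
        assert vs.te_window_density(self.GENE, te, 20000) == 0.0


class TestPrivateSnps:
    def test_private_counting(self):
        snps = [snp(1, "A", "G", line="L1"), snp(1, "A", "G", line="L2"),
                snp(9, "C", "T", line="L1"),
                snp(20, "G", "A", "het", line="L2")]
        counts = vs.private_snp_counts(snps)
        assert counts == {"L1": 1}
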