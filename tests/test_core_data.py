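"""Containers, I/O, gene assignment, LD pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoclines.core_data import (
    FrequencyTable,
    GeneAnnotation,
    Population,
    SNPRecord,
    assign_snps_to_genes,
    average_maf,
    collapse_by_ld,
    frequencies_from_genotypes,
    haplotypes_from_vcf,
    ld_r2,
    read_frequency_table,
    write_frequency_table,
)


def _snp(i, pos=None, chrom="1"):
    return SNPRecord(f"rs{i}", chrom, pos or (i + 1) * 100, "A", "G", "A")


def _table(freq, n_pops=None):
    freq = np.asarray(freq, dtype=float)
    pops = [Population(f"p{j}", 0.0, 0.0, 5) for j in range(freq.shape[1])]
    snps = [_snp(i) for i in range(freq.shape[0])]
    return FrequencyTable(snps=snps, populations=pops, freq=freq)


class TestFrequencyTable:
    def test_round_trip_is_exact(self, tmp_path):
        freq = np.array([[0.25, np.nan], [0.5, 1.0], [0.0, 0.123456789012345]])
        table = _table(freq)
        path = tmp_path / "freq.tsv"
        write_frequency_table(table, path)
        back = read_frequency_table(path, table.populations)
        np.testing.assert_array_equal(back.freq, table.freq)
        assert back.snps == table.snps

    def test_rejects_out_of_range_frequency(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\tallele_a\tallele_b\tancestral\tp0\n"
            "rs1\t1\t100\tA\tG\tA\t1.2\n"
        )
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            read_frequency_table(path)

    def test_rejects_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="no SNPs"):
            read_frequency_table(path)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            FrequencyTable(
                snps=[_snp(0)],
                populations=[Population("p0", 0, 0, 5)],
                freq=np.zeros((2, 1)),
            )


class TestVcfIngestion:
    def _write_vcf(self, path, rows, samples):
        head = (
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AA,Number=1,Type=String,Description="x">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        path.write_text(head + "".join(rows))

    def test_direct_count(self, tmp_path):
        """2 diploids with GT 0/1 and 1/1 give ALT frequency 3/4."""
        path = tmp_path / "a.vcf"
        self._write_vcf(
            path, ["1\t100\trs1\tA\tG\t.\t.\tAA=A\tGT\t0/1\t1/1\n"], ["s1", "s2"]
        )
        table = frequencies_from_genotypes(path, {"s1": "p", "s2": "p"})
        assert table.freq[0, 0] == pytest.approx(0.75)

    def test_all_missing_population_is_nan(self, tmp_path):
        path = tmp_path / "b.vcf"
        self._write_vcf(
            path, ["1\t100\trs1\tA\tG\t.\t.\tAA=A\tGT\t./.\t0/1\n"], ["s1", "s2"]
        )
        table = frequencies_from_genotypes(path, {"s1": "p1", "s2": "p2"})
        assert np.isnan(table.freq[0, table.population_ids.index("p1")])
        assert table.freq[0, table.population_ids.index("p2")] == pytest.approx(0.5)

    def test_matches_hand_count_on_random_genotypes(self, tmp_path, rng):
        gts = rng.integers(0, 2, size=(10, 2))
        row = "1\t100\trs1\tA\tG\t.\t.\tAA=A\tGT\t" + "\t".join(
            f"{a}/{b}" for a, b in gts
        ) + "\n"
        path = tmp_path / "c.vcf"
        self._write_vcf(path, [row], [f"s{i}" for i in range(10)])
        table = frequencies_from_genotypes(path, {f"s{i}": "p" for i in range(10)})
        assert table.freq[0, 0] == pytest.approx(gts.sum() / 20)

    def test_sample_missing_from_pop_map_errors(self, tmp_path):
        path = tmp_path / "d.vcf"
        self._write_vcf(path, ["1\t100\trs1\tA\tG\t.\t.\tAA=A\tGT\t0/1\n"], ["s1"])
        with pytest.raises(ValueError, match="absent"):
            frequencies_from_genotypes(path, {"other": "p"})

    def test_phased_round_trip(self, tmp_path):
        from photoclines.synthdata import SimulationConfig, simulate_haplotypes
        from photoclines.synthdata import write_haplotypes_vcf

        cfg = SimulationConfig(n_haplotypes=8, region_length_kb=40, seed=3)
        panel = simulate_haplotypes(cfg, "p", [])
        path = tmp_path / "hap.vcf"
        write_haplotypes_vcf(panel, path)
        back = haplotypes_from_vcf(path, "p")
        np.testing.assert_array_equal(back.alleles, panel.alleles)
        np.testing.assert_array_equal(back.positions, panel.positions)


class TestAverageMaf:
    def test_plain_mean(self):
        assert average_maf(_table([[0.2, 0.4]]), 0) == pytest.approx(0.3)

    def test_folding(self):
        assert average_maf(_table([[0.9, 0.9]]), 0) == pytest.approx(0.1)

    def test_matches_independent_recomputation(self, rng):
        freqs = rng.uniform(0, 1, size=(1, 52))
        expected = min(freqs.mean(), 1 - freqs.mean())
        assert average_maf(_table(freqs), 0) == pytest.approx(expected, abs=1e-12)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            average_maf(_table([[np.nan, np.nan]]), 0)


class TestGeneAssignment:
    GENE_PLUS = GeneAnnotation("gP", "1", 1000, 2000, "+")
    GENE_MINUS = GeneAnnotation("gM", "1", 1000, 2000, "-")

    @pytest.mark.parametrize(
        "pos,gene,expected",
        [
            (500, GENE_PLUS, True),    # upstream window lower edge (TSS-500)
            (499, GENE_PLUS, False),   # one bp beyond the window
            (1500, GENE_PLUS, True),   # inside transcript
            (2400, GENE_MINUS, True),  # minus-strand upstream mirror
            (2501, GENE_MINUS, False),
            (500, GENE_MINUS, False),  # plus-side window does not apply
        ],
    )
    def test_window_boundaries(self, pos, gene, expected):
        mapping = assign_snps_to_genes([_snp(0, pos=pos)], [gene])
        assert (gene.gene_id in mapping) is expected

    def test_invariant_under_gene_reordering(self, rng):
        snps = [_snp(i, pos=int(p)) for i, p in enumerate(rng.integers(1, 10_000, 50))]
        genes = [
            GeneAnnotation(f"g{k}", "1", int(s), int(s) + 800, "+-"[k % 2])
            for k, s in enumerate(rng.integers(1, 9000, 10))
        ]
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert assign_snps_to_genes(snps, genes) == assign_snps_to_genes(snps, shuffled)

    def test_snp_may_map_to_overlapping_genes(self):
        g1 = GeneAnnotation("g1", "1", 100, 900, "+")
        g2 = GeneAnnotation("g2", "1", 500, 1500, "+")
        mapping = assign_snps_to_genes([_snp(0, pos=600)], [g1, g2])
        assert set(mapping) == {"g1", "g2"}


class TestLd:
    def test_identical_and_complementary_vectors(self):
        v = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        assert ld_r2(v, v) == pytest.approx(1.0)
        assert ld_r2(v, 1 - v) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self, rng):
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        assert ld_r2(a, b) < 0.02

    def test_matches_haplotype_count_formula(self):
        """r2 equals (D / sqrt(pA pa pB pb))^2 from hand counts, 8 haplotypes."""
        a = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        b = np.array([1, 1, 0, 0, 0, 1, 1, 0])
        p_ab = np.mean((a == 1) & (b == 1))
        d = p_ab - a.mean() * b.mean()
        expected = d**2 / (a.mean() * (1 - a.mean()) * b.mean() * (1 - b.mean()))
        assert ld_r2(a, b) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(np.zeros(8), np.array([0, 1] * 4))

    def test_symmetry(self, rng):
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        assert ld_r2(a, b) == pytest.approx(ld_r2(b, a), abs=1e-15)


class TestCollapseByLd:
    def _r2_from_matrix(self, matrix, ids):
        index = {s: i for i, s in enumerate(ids)}
        return lambda a, b: matrix[index[a], index[b]]

    def test_duplicates_collapse_to_one(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0]])
        kept = collapse_by_ld(["a", "b"], self._r2_from_matrix(m, ["a", "b"]), seed=0)
        assert len(kept) == 1

    def test_below_threshold_pair_retained(self):
        m = np.array([[1.0, 0.39], [0.39, 1.0]])
        kept = collapse_by_ld(["a", "b"], self._r2_from_matrix(m, ["a", "b"]), seed=0)
        assert kept == ["a", "b"]

    def test_chain_satisfies_pairwise_audit(self):
        ids = ["a", "b", "c"]
        m = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.5], [0.1, 0.5, 1.0]])
        r2 = self._r2_from_matrix(m, ids)
        kept = collapse_by_ld(ids, r2, seed=0)
        assert all(r2(x, y) < 0.4 for i, x in enumerate(kept) for y in kept[i + 1:])

    def test_deterministic_under_seed(self, rng):
        ids = [f"s{i}" for i in range(12)]
        m = rng.uniform(0, 1, (12, 12))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        r2 = self._r2_from_matrix(m, ids)
        assert collapse_by_ld(ids, r2, seed=7) == collapse_by_ld(ids, r2, seed=7)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_audit_holds_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        ids = [f"s{i}" for i in range(n)]
        m = rng.uniform(0, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        r2 = self._r2_from_matrix(m, ids)
        kept = collapse_by_ld(ids, r2, seed=int(rng.integers(1000)))
        assert kept, "at least one SNP survives"
        assert all(r2(x, y) < 0.4 for i, x in enumerate(kept) for y in kept[i + 1:])


def test_snp_record_validation():
    with pytest.raises(ValueError):
        SNPRecord("rs1", "1", 100, "A", "A")
    with pytest.raises(ValueError):
        SNPRecord("rs1", "1", 0, "A", "G")
    with pytest.raises(ValueError):
        SNPRecord("rs1", "1", 100, "A", "G", ancestral="T")


def test_population_validation():
    with pytest.raises(ValueError):
        Population("p", 95.0, 0.0, 5)
    with pytest.raises(ValueError):
        Population("p", 0.0, 0.0, 0)
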