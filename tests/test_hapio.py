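"""I/O, genetic map, gene intervals and QC filtering."""

import numpy as np
import pandas as pd
import pytest

from sweepscan import hapio
from sweepscan.hapio import GeneticMap, HapIOError, qc_filter

from conftest import make_hap

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\n"
)


def write_vcf(tmp_path, body, name="test.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadPhasedVcf:
    def test_basic_matrix_construction(self, tmp_path):
        body = (
            "chr1\t100\trs1\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|1\n"
            "chr1\t200\trs2\tC\tT\t.\tPASS\tAA=C\tGT\t0|0\t0|1\n"
            "chr1\t300\trs3\tG\tA\t.\tPASS\tAA=G\tGT\t1|0\t0|0\n"
        )
        hap, report = hapio.read_phased_vcf(write_vcf(tmp_path, body))
        assert hap.haplotypes.shape == (4, 3)
        assert report.n_kept == 3
        np.testing.assert_array_equal(
            hap.haplotypes, [[0, 0, 1], [1, 0, 0], [1, 0, 0], [1, 1, 0]]
        )

    def test_unphased_genotype_is_hard_error_naming_record(self, tmp_path):
        body = "chr1\t100\trs1\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0/1\n"
        with pytest.raises(HapIOError, match="chr1:100"):
            hapio.read_phased_vcf(write_vcf(tmp_path, body))

    def test_aa_equals_alt_flips_polarity(self, tmp_path):
        # AA=G (the ALT): column must be flipped so 1 = derived (= REF here)
        body = "chr1\t100\trs1\tA\tG\t.\tPASS\tAA=G\tGT\t0|1\t1|1\n"
        hap, _ = hapio.read_phased_vcf(write_vcf(tmp_path, body))
        np.testing.assert_array_equal(hap.haplotypes[:, 0], [1, 0, 0, 0])
        assert hap.variants.loc[0, "ancestral_allele"] == "G"
        assert hap.variants.loc[0, "derived_allele"] == "A"

    def test_missing_aa_flags_unpolarizable_but_keeps_variant(self, tmp_path):
        body = (
            "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "chr1\t200\trs2\tC\tT\t.\tPASS\tAA=C\tGT\t0|0\t0|1\n"
        )
        hap, report = hapio.read_phased_vcf(write_vcf(tmp_path, body))
        assert hap.n_variants == 2
        assert not hap.variants.loc[0, "polarizable"]
        assert report.n_unpolarizable == 1

    def test_multiallelic_skipped_with_count(self, tmp_path):
        body = (
            "chr1\t100\trs1\tA\tG,T\t.\tPASS\tAA=A\tGT\t0|1\t2|1\n"
            "chr1\t200\trs2\tC\tT\t.\tPASS\tAA=C\tGT\t0|0\t0|1\n"
        )
        hap, report = hapio.read_phased_vcf(write_vcf(tmp_path, body))
        assert hap.n_variants == 1
        assert report.n_multiallelic_skipped == 1

    def test_polarity_invariance_under_ref_alt_relabel(self, tmp_path):
        # same data with REF/ALT swapped (and GT recoded) but identical AA
        a = "chr1\t100\trs1\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|1\n"
        b = "chr1\t100\trs1\tG\tA\t.\tPASS\tAA=A\tGT\t1|0\t0|0\n"
        hap_a, _ = hapio.read_phased_vcf(write_vcf(tmp_path, a, "a.vcf"))
        hap_b, _ = hapio.read_phased_vcf(write_vcf(tmp_path, b, "b.vcf"))
        np.testing.assert_array_equal(hap_a.haplotypes, hap_b.haplotypes)

    def test_round_trip_preserves_everything(self, tmp_path):
        rng = np.random.default_rng(5)
        m = rng.integers(0, 2, size=(8, 20)).astype(np.int8)
        m[rng.random(m.shape) < 0.05] = -1
        hap = make_hap(m, label="roundtrip")
        out = tmp_path / "rt.vcf"
        hapio.write_phased_vcf(hap, out)
        back, _ = hapio.read_phased_vcf(out, population_label="roundtrip")
        np.testing.assert_array_equal(back.haplotypes, hap.haplotypes)
        pd.testing.assert_frame_equal(
            back.variants[["chrom", "pos_bp", "ancestral_allele", "derived_allele"]],
            hap.variants[["chrom", "pos_bp", "ancestral_allele", "derived_allele"]],
        )


class TestGeneticMap:
    def test_linear_interpolation_and_anchors(self):
        gmap = GeneticMap({"chr1": ([1_000_000, 2_000_000], [1.0, 2.0])})
        assert gmap.interpolate("chr1", 1_500_000) == pytest.approx(1.5)
        assert gmap.interpolate("chr1", 1_000_000) == pytest.approx(1.0)
        # midpoint = arithmetic mean of anchor cMs
        assert gmap.interpolate("chr1", 1_500_000) == pytest.approx((1.0 + 2.0) / 2)

    def test_extrapolation_uses_flanking_slope(self):
        gmap = GeneticMap({"chr1": ([1_000_000, 2_000_000], [1.0, 2.0])})
        assert gmap.interpolate("chr1", 500_000) == pytest.approx(0.5)
        assert gmap.interpolate("chr1", 2_500_000) == pytest.approx(2.5)

    def test_monotone_in_position(self):
        rng = np.random.default_rng(0)
        bp = np.sort(rng.choice(10_000_000, size=20, replace=False))
        cm = np.cumsum(rng.random(20))
        gmap = GeneticMap({"chr1": (bp, cm)})
        q = np.sort(rng.integers(0, 11_000_000, size=200))
        vals = gmap.interpolate("chr1", q)
        assert np.all(np.diff(vals) >= 0)

    def test_single_anchor_rejected(self):
        with pytest.raises(HapIOError, match=">=2"):
            GeneticMap({"chr1": ([1_000_000], [1.0])})

    def test_decreasing_cm_rejected(self):
        with pytest.raises(HapIOError, match="decreasing"):
            GeneticMap({"chr1": ([1, 2, 3], [0.0, 1.0, 0.5])})

    def test_duplicate_bp_collapsed_to_first(self):
        gmap = GeneticMap({"chr1": ([1, 1, 3], [0.0, 5.0, 1.0])})
        assert gmap.interpolate("chr1", 1) == pytest.approx(0.0)

    def test_unknown_chromosome_errors(self):
        gmap = GeneticMap({"chr1": ([1, 2], [0.0, 1.0])})
        with pytest.raises(HapIOError, match="chr9"):
            gmap.interpolate("chr9", 1)

    def test_file_round_trip(self, tmp_path):
        gmap = GeneticMap({"chr1": ([1, 1000], [0.0, 0.5]), "chr2": ([5, 600], [0.1, 0.9])})
        hapio.write_genetic_map(gmap, tmp_path / "map.tsv")
        back = hapio.read_genetic_map(tmp_path / "map.tsv")
        for chrom in gmap.chromosomes:
            np.testing.assert_array_equal(back.anchors[chrom][0], gmap.anchors[chrom][0])
            np.testing.assert_allclose(back.anchors[chrom][1], gmap.anchors[chrom][1])


class TestGeneBed:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t999\t2000\tG1\n")
        genes = hapio.read_gene_bed(p)
        assert genes.loc[0, "start_bp"] == 1000
        assert genes.loc[0, "end_bp"] == 2000

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t10\tG1\nchr1\t20\t30\tG1\n")
        with pytest.raises(HapIOError, match="duplicate"):
            hapio.read_gene_bed(p)

    def test_zero_length_interval_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t100\tG1\n")
        with pytest.raises(HapIOError, match="length"):
            hapio.read_gene_bed(p)

    def test_missing_name_column_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t10\n")
        with pytest.raises(HapIOError, match="4 columns"):
            hapio.read_gene_bed(p)


class TestQcFilter:
    def _hap_with_missing(self):
        # 100 individuals x 4 SNPs; SNP0 missing in 3 individuals (3% > 2%)
        rng = np.random.default_rng(2)
        m = rng.integers(0, 2, size=(200, 4)).astype(np.int8)
        for ind in (0, 1, 2):
            m[2 * ind, 0] = -1
        return make_hap(m)

    def test_snp_missingness_threshold(self):
        filtered, report = qc_filter(self._hap_with_missing())
        assert report.n_snps_missing_removed == 1
        assert filtered.n_variants <= 3

    def test_individual_missingness_threshold(self):
        # individual 0 missing 6% of genotypes (3 of 50 SNPs) -> removed
        rng = np.random.default_rng(3)
        m = rng.integers(0, 2, size=(40, 50)).astype(np.int8)
        m[0, :3] = -1
        hap = make_hap(m)
        # snp_missing_max relaxed so the missing SNPs survive step 1 and the
        # 6%-missing individual is what gets removed
        filtered, report = qc_filter(hap, snp_missing_max=0.10, ind_missing_max=0.05)
        assert report.n_individuals_removed == 1
        assert filtered.n_individuals == 19

    def test_maf_threshold(self):
        # 100 individuals; SNP0 at MAF 0.005 (1/200) removed, SNP1 at 0.05 kept
        m = np.zeros((200, 2), dtype=np.int8)
        m[0, 0] = 1
        m[:10, 1] = 1
        filtered, report = qc_filter(make_hap(m))
        assert report.n_snps_maf_removed == 1
        assert filtered.n_variants == 1
        assert filtered.variants.loc[0, "pos_bp"] == 2000

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        m = rng.integers(0, 2, size=(60, 80)).astype(np.int8)
        m[rng.random(m.shape) < 0.02] = -1
        once, _ = qc_filter(make_hap(m))
        twice, _ = qc_filter(once)
        np.testing.assert_array_equal(once.haplotypes, twice.haplotypes)
        pd.testing.assert_frame_equal(once.variants, twice.variants)

    def test_all_snps_removed_errors(self):
        m = np.zeros((10, 2), dtype=np.int8)  # every SNP monomorphic -> MAF 0
        with pytest.raises(HapIOError):
            qc_filter(make_hap(m))

    def test_bad_threshold_rejected(self):
        m = np.zeros((4, 2), dtype=np.int8)
        m[0] = 1
        with pytest.raises(ValueError):
            qc_filter(make_hap(m), maf_min=1.5)


class TestIntersectVariants:
    def test_common_subset_in_genomic_order(self):
        a = make_hap(np.ones((4, 3), dtype=np.int8), positions=[100, 200, 300])
        b = make_hap(np.zeros((4, 2), dtype=np.int8), positions=[200, 300])
        out = hapio.intersect_variants({"a": a, "b": b})
        assert out["a"].variants["pos_bp"].tolist() == [200, 300]
        assert out["b"].variants["pos_bp"].tolist() == [200, 300]


class TestOutgroupPolarizer:
    def test_major_outgroup_allele_becomes_ancestral(self):
        target = make_hap(np.array([[0, 1], [1, 1], [0, 0], [1, 0]], dtype=np.int8))
        # outgroup: SNP0 derived-major (freq .75 > .5) -> flip; SNP1 minor -> keep
        outgroup = make_hap(
            np.array([[1, 0], [1, 0], [1, 1], [0, 0]], dtype=np.int8), label="out"
        )
        flipped = hapio.polarize_by_outgroup(target, outgroup)
        np.testing.assert_array_equal(flipped.haplotypes[:, 0], [1, 0, 1, 0])
        np.testing.assert_array_equal(flipped.haplotypes[:, 1], target.haplotypes[:, 1])
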