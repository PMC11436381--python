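"""Genome geometry, interval arithmetic and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcalite import (
    ChromosomeGeometry,
    GeneIntervalSet,
    GenomeBuild,
    grch37,
    interval_overlap,
    read_bed,
    read_sample_vcf,
    simulate_phased_sample,
    toy_genome,
    write_calls_bed,
    write_sample_vcf,
)
from mcalite.caller import MosaicCall
from mcalite.io import VcfFormatError
from mcalite.sample import ChromosomeData, SnpRecord


class TestGenomeBuild:
    def test_arms_partition_chromosome_minus_centromere(self, genome):
        for c in genome:
            assert c.p_arm == (1, c.cen_start - 1)
            assert c.q_arm == (c.cen_end + 1, c.length)
            assert (c.p_arm[1] - c.p_arm[0] + 1) + (c.cen_end - c.cen_start + 1) + (
                c.q_arm[1] - c.q_arm[0] + 1
            ) == c.length

    @pytest.mark.parametrize(
        "length,cs,ce",
        [(0, 1, 2), (100, 1, 5), (100, 50, 100), (100, 60, 40)],
    )
    def test_invalid_geometry_rejected(self, length, cs, ce):
        with pytest.raises(ValueError):
            ChromosomeGeometry("bad", length, cs, ce)

    def test_grch37_has_expected_chromosome_lengths(self):
        g = grch37()
        assert g["13"].length == 115169878
        assert g["X"].length == 155270560

    def test_yaml_round_trip(self, genome, tmp_path):
        path = str(tmp_path / "build.yaml")
        genome.to_yaml(path)
        again = GenomeBuild.from_yaml(path)
        assert again.names() == genome.names()
        assert again["3"].cen_start == genome["3"].cen_start


class TestIntervalOverlap:
    def test_identical_intervals(self):
        assert interval_overlap(("1", 10, 20), ("1", 10, 20)) == (1.0, 1.0)

    def test_disjoint_and_cross_chromosome(self):
        assert interval_overlap(("1", 1, 10), ("1", 11, 20)) == (0.0, 0.0)
        assert interval_overlap(("1", 1, 10), ("2", 1, 10)) == (0.0, 0.0)

    def test_half_overlap_matches_brute_force(self):
        a, b = ("1", 1, 100), ("1", 51, 150)
        shared = len(set(range(1, 101)) & set(range(51, 151)))
        fa, fb = interval_overlap(a, b)
        assert fa == shared / 100 and fb == shared / 100 == 0.5

    @settings(max_examples=200, deadline=None)
    @given(
        s1=st.integers(1, 50), l1=st.integers(0, 50),
        s2=st.integers(1, 50), l2=st.integers(0, 50),
    )
    def test_matches_set_arithmetic(self, s1, l1, s2, l2):
        a, b = ("1", s1, s1 + l1), ("1", s2, s2 + l2)
        shared = len(set(range(s1, s1 + l1 + 1)) & set(range(s2, s2 + l2 + 1)))
        fa, fb = interval_overlap(a, b)
        assert fa == pytest.approx(shared / (l1 + 1))
        assert fb == pytest.approx(shared / (l2 + 1))


class TestVcfIO:
    def test_read_write_read_is_fixed_point(self, genome, tmp_path):
        sample, _ = simulate_phased_sample(chroms=["3"], seed=3)
        p1, p2 = str(tmp_path / "a.vcf"), str(tmp_path / "b.vcf")
        write_sample_vcf(sample, p1, genome)
        again = read_sample_vcf(p1, genome)
        write_sample_vcf(again, p2, genome)
        data1 = [l for l in open(p1) if not l.startswith("#")]
        data2 = [l for l in open(p2) if not l.startswith("#")]
        assert data1 == data2
        cd0, cd1 = sample["3"], again["3"]
        np.testing.assert_array_equal(cd0.pos, cd1.pos)
        np.testing.assert_array_equal(cd0.gt, cd1.gt)
        np.testing.assert_allclose(cd0.baf, cd1.baf, atol=1e-4)

    def test_genotype_mapping_from_baf_extremes(self, genome, tmp_path):
        path = str(tmp_path / "tiny.vcf")
        cd = ChromosomeData(
            pos=np.array([1000, 2000, 3000]),
            gt=np.array([0, 1, 2], dtype=np.int8),
            phased=np.array([False, True, False]),
            hap1=np.array([0, 1, 1], dtype=np.int8),
            hap2=np.array([0, 0, 1], dtype=np.int8),
            baf=np.array([0.0, 0.5, 1.0]),
            lrr=np.zeros(3),
        )
        from mcalite.sample import SampleArray

        write_sample_vcf(SampleArray("x", "saliva", {"3": cd}), path, genome)
        s = read_sample_vcf(path, genome)
        assert list(s["3"].gt) == [0, 1, 2]
        assert s["3"].phased[1] and s["3"].hap1[1] == 1

    def test_baf_out_of_bounds_names_the_record(self, genome, tmp_path):
        path = str(tmp_path / "bad.vcf")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=3,length=30000000>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n')
            fh.write('##FORMAT=<ID=BAF,Number=1,Type=Float,Description="b">\n')
            fh.write('##FORMAT=<ID=LRR,Number=1,Type=Float,Description="l">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS_saliva\n")
            fh.write("3\t5000\t.\tA\tC\t.\t.\t.\tGT:BAF:LRR\t0|1:1.2:0.0\n")
        with pytest.raises(ValueError, match="3:5000"):
            read_sample_vcf(path, genome)

    def test_missing_format_field_raises(self, genome, tmp_path):
        path = str(tmp_path / "nolrr.vcf")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=3,length=30000000>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n')
            fh.write('##FORMAT=<ID=BAF,Number=1,Type=Float,Description="b">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS_saliva\n")
            fh.write("3\t5000\t.\tA\tC\t.\t.\t.\tGT:BAF\t0|1:0.5\n")
        with pytest.raises(VcfFormatError, match="LRR"):
            read_sample_vcf(path, genome)

    def test_snp_record_rejects_invalid_baf(self):
        with pytest.raises(ValueError):
            SnpRecord("3", 1, "A", "C", 1, True, 1, 0, 1.2, 0.0)


class TestBed:
    def _call(self, chrom, start, end):
        return MosaicCall(
            individual="x", tissue="saliva", chrom=chrom, start=start, end=end,
            n_snps=10, n_hets=5, bdev=0.1, lrr_mean=0.0, lrr_se=0.01,
            lod=50.0, phase_concordance=0.9, type="loss", cell_fraction=0.3,
        )

    def test_bed_is_zero_based_half_open(self, tmp_path):
        g = grch37()
        path = str(tmp_path / "calls.bed")
        write_calls_bed([self._call("22", 45311891, 51304566)], path, g)
        line = [l for l in open(path) if not l.startswith("#")][0].split("\t")
        assert (line[0], int(line[1]), int(line[2])) == ("22", 45311890, 51304566)

    def test_sorted_output_and_empty_file_header(self, genome, tmp_path):
        path = str(tmp_path / "two.bed")
        write_calls_bed(
            [self._call("3", 2_000_000, 3_000_000), self._call("3", 100, 200)],
            path, genome,
        )
        starts = [int(l.split("\t")[1]) for l in open(path) if not l.startswith("#")]
        assert starts == sorted(starts)
        empty = str(tmp_path / "empty.bed")
        write_calls_bed([], empty, genome)
        assert open(empty).read().startswith("#")

    def test_unknown_chromosome_rejected(self, genome, tmp_path):
        with pytest.raises(ValueError, match="chr99"):
            write_calls_bed([self._call("chr99", 1, 10)], str(tmp_path / "x.bed"), genome)

    def test_bed_import_restores_one_based_coordinates(self, tmp_path):
        path = str(tmp_path / "genes.bed")
        open(path, "w").write("3\t999\t2000\tGENE1\n")
        gs = read_bed(path)
        assert gs.intervals == [("3", 1000, 2000, "GENE1")]


def test_gene_interval_set_validation(genome):
    gs = GeneIntervalSet([("3", 100, 200, "g1")])
    gs.validate_against(genome)
    assert gs.any_overlap("3", 150, 300)
    assert not gs.any_overlap("3", 201, 300)
    with pytest.raises(ValueError):
        GeneIntervalSet([("3", 200, 100, "bad")])
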