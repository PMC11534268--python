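"""Readers, harmonization, and the SNP-to-gene assignment rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tapa import gwas_io
from tests.conftest import make_panel, make_study

COLMAP = {"snp": "SNP", "chrom": "CHR", "pos": "BP", "beta": "BETA",
          "se": "SE", "p": "P", "z": "Z",
          "effect_allele": "A1", "other_allele": "A2"}


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSummary:
    def test_basic_read_and_z(self, tmp_path):
        p = write(tmp_path, "s.tsv",
                  "SNP\tCHR\tBP\tBETA\tSE\tP\n"
                  "rs1\t1\t100\t0.1\t0.05\t0.0455\n"
                  "rs2\t1\t200\t-0.2\t0.1\t0.0455\n"
                  "rs3\t2\t300\t0.0\t0.1\t1.0\n")
        s = gwas_io.read_summary(p, COLMAP, n_cases=10, n_controls=10)
        assert s.z[0] == pytest.approx(2.0)
        assert len(s.table) == 3

    def test_bad_rows_dropped(self, tmp_path):
        p = write(tmp_path, "s.tsv",
                  "SNP\tCHR\tBP\tBETA\tSE\tP\n"
                  "rs1\t1\t100\t0.1\t0.0\t0.5\n"   # se = 0
                  "rs2\t1\t200\t0.1\t0.05\t0.5\n"
                  "rs3\t1\t300\tnot_a_number\t0.05\t0.5\n")
        s = gwas_io.read_summary(p, COLMAP)
        assert list(s.table["snp"]) == ["rs2"]

    def test_p_only_fatal_unless_z(self, tmp_path):
        p = write(tmp_path, "s.tsv", "SNP\tCHR\tBP\tP\nrs1\t1\t100\t0.5\n")
        with pytest.raises(ValueError, match="beta"):
            gwas_io.read_summary(p, COLMAP)
        p2 = write(tmp_path, "s2.tsv", "SNP\tCHR\tBP\tZ\nrs1\t1\t100\t2.0\n")
        s = gwas_io.read_summary(p2, COLMAP)
        assert s.z[0] == pytest.approx(2.0)
        assert s.table["p"][0] == pytest.approx(0.0455, abs=1e-4)

    def test_missing_required_column_fatal(self, tmp_path):
        p = write(tmp_path, "s.tsv", "SNP\tBETA\tSE\nrs1\t0.1\t0.1\n")
        with pytest.raises(ValueError, match="chrom"):
            gwas_io.read_summary(p, COLMAP)

    def test_all_rows_invalid_fatal(self, tmp_path):
        p = write(tmp_path, "s.tsv",
                  "SNP\tCHR\tBP\tBETA\tSE\tP\nrs1\t1\t100\t0.1\t-1\t0.5\n")
        with pytest.raises(ValueError, match="no valid"):
            gwas_io.read_summary(p, COLMAP)

    def test_comma_delimited_autodetect(self, tmp_path):
        p = write(tmp_path, "s.csv",
                  "SNP,CHR,BP,BETA,SE,P\nrs1,1,100,0.1,0.05,0.0455\n")
        s = gwas_io.read_summary(p, COLMAP)
        assert len(s.table) == 1


class TestAssignment:
    GENES = pd.DataFrame({"gene": ["gA", "gB"], "chrom": ["1", "1"],
                          "start": [1000, 40_000], "end": [2000, 41_000]})

    def test_window_rule_inclusive(self):
        snps = pd.DataFrame({"snp": ["r1"], "chrom": ["1"], "pos": [950]})
        m = gwas_io.assign_snps_to_genes(self.GENES, snps, window=50_000)
        assert "r1" in m.assignments["gA"]

    def test_snp_in_two_windows_assigned_to_both(self):
        snps = pd.DataFrame({"snp": ["r1"], "chrom": ["1"], "pos": [21_000]})
        m = gwas_io.assign_snps_to_genes(self.GENES, snps, window=50_000)
        assert "r1" in m.assignments["gA"] and "r1" in m.assignments["gB"]

    def test_window_zero_boundary(self):
        snps = pd.DataFrame({"snp": ["r0", "r1"], "chrom": ["1", "1"],
                             "pos": [999, 1000]})
        m = gwas_io.assign_snps_to_genes(self.GENES, snps, window=0)
        assert m.assignments["gA"] == ["r1"]

    def test_empty_gene_excluded_from_J(self):
        snps = pd.DataFrame({"snp": ["r1"], "chrom": ["1"], "pos": [1500]})
        m = gwas_io.assign_snps_to_genes(self.GENES, snps, window=0)
        assert m.assignments["gB"] == []
        assert m.J == 1

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_window_monotone(self, seed):
        rng = np.random.default_rng(seed)
        snps = pd.DataFrame({
            "snp": [f"r{i}" for i in range(30)],
            "chrom": "1",
            "pos": rng.integers(1, 100_000, 30),
        })
        w1, w2 = sorted(rng.integers(0, 60_000, 2))
        m1 = gwas_io.assign_snps_to_genes(self.GENES, snps, window=int(w1))
        m2 = gwas_io.assign_snps_to_genes(self.GENES, snps, window=int(w2))
        for g in m1.assignments:
            assert set(m1.assignments[g]) <= set(m2.assignments[g])


class TestAssignmentFile:
    def test_read_and_dedup(self, tmp_path):
        p = write(tmp_path, "a.tsv", "geneA\trs1\ngeneA\trs2\ngeneA\trs1\n")
        m = gwas_io.read_assignment_file(p)
        assert m.assignments["geneA"] == ["rs1", "rs2"]

    def test_unknown_snps_dropped(self, tmp_path):
        p = write(tmp_path, "a.tsv", "geneA\trs1\ngeneA\trsX\n")
        m = gwas_io.read_assignment_file(p, known_snps={"rs1"})
        assert m.assignments["geneA"] == ["rs1"]

    def test_empty_fatal(self, tmp_path):
        p = write(tmp_path, "a.tsv", "")
        with pytest.raises(ValueError, match="empty"):
            gwas_io.read_assignment_file(p)


class TestGmt:
    def test_sizes_and_malformed(self, tmp_path):
        p = write(tmp_path, "p.gmt",
                  "pw1\tdesc\tg1\tg2\tg3\n"
                  "bad_line_two_fields\tdesc\n"
                  "pw2\tdesc\tg1\tg2\tg3\tg4\tg5\n")
        pws = gwas_io.read_gmt(p)
        assert [len(pw.genes) for pw in pws] == [3, 5]

    def test_max_genes_filter(self, tmp_path):
        big = "\t".join(f"g{i}" for i in range(600))
        p = write(tmp_path, "p.gmt", f"small\td\tg1\tg2\nbig\td\t{big}\n")
        pws = gwas_io.read_gmt(p, max_genes=500)
        assert [pw.name for pw in pws] == ["small"]

    def test_duplicate_gene_counted_once(self, tmp_path):
        p = write(tmp_path, "p.gmt", "pw\td\tg1\tg1\tg2\n")
        assert len(gwas_io.read_gmt(p)[0].genes) == 2


class TestBed:
    def test_bed_converted_to_one_based(self, tmp_path):
        p = write(tmp_path, "g.bed", "1\t999\t2000\tgA\n")
        genes = gwas_io.read_gene_annotation(p)
        assert genes.loc[0, "start"] == 1000
        assert genes.loc[0, "end"] == 2000


class TestHarmonization:
    def _study(self, ea, oa, beta=0.1):
        s = make_study(snps=["rs1"], beta=[beta], se=[0.05])
        s.table["effect_allele"] = [ea]
        s.table["other_allele"] = [oa]
        return s

    def test_swap_flips_beta(self):
        panel = make_panel(snps=["rs1"])  # ref=A alt=G
        out = gwas_io.harmonize_study_with_panel(self._study("A", "G"), panel)
        assert out.table["beta"][0] == pytest.approx(-0.1)
        assert out.table["effect_allele"][0] == "G"

    def test_matching_untouched_and_involutive(self):
        panel = make_panel(snps=["rs1"])
        once = gwas_io.harmonize_study_with_panel(self._study("G", "A"), panel)
        twice = gwas_io.harmonize_study_with_panel(once, panel)
        assert once.table["beta"][0] == pytest.approx(0.1)
        pd.testing.assert_frame_equal(once.table, twice.table)
        # flip case is involutive too
        flip_once = gwas_io.harmonize_study_with_panel(self._study("A", "G"), panel)
        flip_twice = gwas_io.harmonize_study_with_panel(flip_once, panel)
        pd.testing.assert_frame_equal(flip_once.table, flip_twice.table)

    def test_mismatch_dropped(self):
        panel = make_panel(snps=["rs1"])
        out = gwas_io.harmonize_study_with_panel(self._study("C", "T"), panel)
        assert len(out.table) == 0

    def test_ambiguous_flagged_or_dropped(self):
        g = np.random.default_rng(0).binomial(2, 0.3, (50, 1)).astype(float)
        panel = make_panel(snps=["rs1"], genotypes=g)
        panel.snp_index.loc[0, ["ref", "alt"]] = ["A", "T"]
        kept = gwas_io.harmonize_study_with_panel(self._study("T", "A"), panel)
        assert bool(kept.table["ambiguous"][0])
        dropped = gwas_io.harmonize_study_with_panel(
            self._study("T", "A"), panel, drop_ambiguous=True
        )
        assert len(dropped.table) == 0


class TestPanels:
    def test_text_roundtrip(self, tmp_path, rng):
        g = rng.binomial(2, 0.4, size=(20, 3))
        np.savetxt(tmp_path / "g.txt", g, fmt="%d")
        pd.DataFrame({
            "snp": ["rs1", "rs2", "rs3"], "chrom": "1",
            "pos": [1, 2, 3], "ref": "A", "alt": "G",
        }).to_csv(tmp_path / "i.tsv", sep="\t", index=False)
        panel = gwas_io.read_panel_text(tmp_path / "g.txt", tmp_path / "i.tsv", "EUR")
        np.testing.assert_array_equal(panel.genotypes, g)
        assert panel.n_individuals == 20

    def test_vcf_read(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FILTER=<ID=PASS,Description="ok">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\tI2\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.\n"
            "1\t300\trs3\tA\tGT\t.\tPASS\t.\tGT\t0/0\t0/1\n"  # indel: skipped
        )
        path = tmp_path / "p.vcf"
        path.write_text(vcf)
        panel = gwas_io.read_panel_vcf(path, "EUR")
        assert list(panel.snp_index["snp"]) == ["rs1", "rs2"]
        np.testing.assert_array_equal(panel.genotypes[:, 0], [1.0, 2.0])
        assert np.isnan(panel.genotypes[1, 1])

    def test_maf(self):
        panel = make_panel(snps=["rs1"], genotypes=np.array([[2.], [2.], [1.], [1.]]))
        assert panel.maf()[0] == pytest.approx(0.25)


def test_study_summary_validation():
    with pytest.raises(ValueError, match="duplicate"):
        make_study(snps=["rs1", "rs1", "rs2"])
    with pytest.raises(ValueError, match="positive"):
        make_study(se=[0.1, -0.1, 0.1])
    with pytest.raises(ValueError, match="lambda"):
        make_study(lambda_gc=0.5)
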