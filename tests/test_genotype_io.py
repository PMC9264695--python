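import numpy as np
import pandas as pd
import pytest

from marksel.discrimination import MarkerSolution
from marksel.genotype_io import (
    export_cervus,
    filter_maf,
    load_panel,
    prune_spacing_ld,
    write_dosage_tsv,
)
from marksel.simulate import OffspringSet

from conftest import make_map, make_panel


def write_tsv(path, marker_ids, columns):
    """columns: {sample: [values]}; values already strings."""
    df = pd.DataFrame(columns, index=marker_ids)
    df.index.name = "marker"
    df.to_csv(path, sep="\t")


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1,length=1000000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tMOTHER\tF1\tF2\n"
)


class TestLoadVcf:
    def test_orientation_counts_non_maternal_allele(self, tmp_path):
        # mother GG (hom ref), F1 GA, F2 AA -> dosages 1 and 2
        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chr1\t100\tsnp1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        panel = load_panel(vcf, "vcf", "MOTHER")
        assert panel.individual_ids == ["F1", "F2"]
        assert panel.marker_ids == ["snp1"]
        assert panel.dosages.tolist() == [[1.0], [2.0]]

    def test_mother_alt_homozygote_is_flipped(self, tmp_path):
        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chr1\t100\tsnp1\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\n"
        )
        panel = load_panel(vcf, "vcf", "MOTHER")
        # F1 het stays 1; F2 hom-ref becomes 2 copies of the non-maternal allele
        assert panel.dosages.tolist() == [[1.0], [2.0]]

    def test_mother_het_sites_and_multiallelic_dropped(self, tmp_path):
        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chr1\t100\tsnp1\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/1\t1/1\n"
            + "chr1\t200\tsnp2\tG\tA,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            + "chr1\t300\tsnp3\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        panel = load_panel(vcf, "vcf", "MOTHER")
        assert panel.marker_ids == ["snp3"]

    def test_half_call_treated_missing(self, tmp_path):
        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chr1\t100\tsnp1\tG\tA\t.\tPASS\t.\tGT\t0/0\t./1\t1/1\n"
        )
        panel = load_panel(vcf, "vcf", "MOTHER")
        assert np.isnan(panel.dosages[0, 0])

    def test_all_sites_uninformative_is_fatal(self, tmp_path):
        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            VCF_HEADER + "chr1\t100\tsnp1\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/1\t1/1\n"
        )
        with pytest.raises(ValueError, match="no informative loci"):
            load_panel(vcf, "vcf", "MOTHER")


class TestLoadDosageTsv:
    def test_mother_het_marker_removed(self, tmp_path):
        path = tmp_path / "dose.tsv"
        write_tsv(path, ["m1", "m2"], {"MOTHER": ["1", "0"], "A": ["2", "1"], "B": ["0", "2"]})
        panel = load_panel(path, "dosage-tsv", "MOTHER")
        assert panel.marker_ids == ["m2"]

    def test_out_of_domain_value_rejected(self, tmp_path):
        path = tmp_path / "dose.tsv"
        write_tsv(path, ["m1"], {"MOTHER": ["0"], "A": ["3"], "B": ["0"]})
        with pytest.raises(ValueError, match="outside"):
            load_panel(path, "dosage-tsv", "MOTHER")

    def test_unknown_mother_names_available_ids(self, tmp_path):
        path = tmp_path / "dose.tsv"
        write_tsv(path, ["m1"], {"A": ["0"], "B": ["2"]})
        with pytest.raises(ValueError, match="'A'"):
            load_panel(path, "dosage-tsv", "NOPE")

    def test_both_missing_tokens_accepted(self, tmp_path):
        path = tmp_path / "dose.tsv"
        write_tsv(path, ["m1"], {"MOTHER": ["0"], "A": ["NA"], "B": ["."]})
        panel = load_panel(path, "dosage-tsv", "MOTHER")
        assert np.isnan(panel.dosages).all()

    def test_mother_is_candidate_flag(self, tmp_path):
        path = tmp_path / "dose.tsv"
        write_tsv(path, ["m1"], {"MOTHER": ["0"], "A": ["2"], "B": ["1"]})
        panel = load_panel(path, "dosage-tsv", "MOTHER", mother_is_candidate=True)
        assert panel.individual_ids == ["MOTHER", "A", "B"]


def test_dosage_tsv_round_trip_preserves_missing(tmp_path):
    panel = make_panel([[0, 1, None], [2, None, 1], [1, 2, 0]])
    path = tmp_path / "rt.tsv"
    write_dosage_tsv(panel, path, include_mother=True)
    back = load_panel(path, "dosage-tsv", "MOTHER")
    assert back.individual_ids == panel.individual_ids
    assert back.marker_ids == panel.marker_ids
    np.testing.assert_array_equal(back.dosages, panel.dosages)


def test_orientation_invariant_mother_zero_everywhere(tmp_path):
    rng = np.random.default_rng(5)
    dosages = rng.integers(0, 3, size=(6, 30)).astype(str)
    cols = {"MOTHER": dosages[0], "A": dosages[1], "B": dosages[2],
            "C": dosages[3], "D": dosages[4], "E": dosages[5]}
    path = tmp_path / "orient.tsv"
    write_tsv(path, [f"m{k}" for k in range(30)], cols)
    panel = load_panel(path, "dosage-tsv", "MOTHER")
    assert (panel.maternal_dosages == 0).all()
    assert panel.n_markers > 0


class TestFilterMaf:
    def test_rare_marker_removed(self):
        panel = make_panel([[0, 0], [0, 0], [0, 2], [1, 2]])
        out = filter_maf(panel, 0.2)
        assert out.marker_ids == ["M1"]  # M0 maf = 1/8

    def test_zero_threshold_is_identity(self, toy_panel):
        out = filter_maf(toy_panel, 0.0)
        assert out.marker_ids == toy_panel.marker_ids

    def test_minor_allele_is_rarer_side(self):
        # dosages (2,2,1,0): freq 5/8, maf 3/8 = 0.375 -> kept at 0.2
        panel = make_panel([[2, 0], [2, 0], [1, 0], [0, 2]])
        out = filter_maf(panel, 0.2)
        assert "M0" in out.marker_ids

    def test_missing_excluded_from_denominator(self):
        # 2 typed of 4: freq = 1/4 -> maf 0.25
        panel = make_panel([[1, 0], [0, 0], [None, 0], [None, 2]])
        out = filter_maf(panel, 0.25)
        assert "M0" in out.marker_ids

    def test_all_removed_is_fatal(self):
        panel = make_panel([[0, 0], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="every marker"):
            filter_maf(panel, 0.1)


class TestPruneSpacingLd:
    def test_close_pair_later_removed(self):
        panel = make_panel([[0, 0], [1, 2], [2, 1], [0, 1]])
        mmap = make_map({"M0": ("chr1", 1_000), "M1": ("chr1", 6_000)}, {"chr1": 100_000})
        out = prune_spacing_ld(panel, mmap)
        assert out.marker_ids == ["M0"]

    def test_high_r2_later_removed(self):
        panel = make_panel([[0, 0], [1, 1], [2, 2], [0, 0]])  # identical columns
        mmap = make_map({"M0": ("chr1", 1_000), "M1": ("chr1", 51_000)}, {"chr1": 100_000})
        out = prune_spacing_ld(panel, mmap)
        assert out.marker_ids == ["M0"]

    def test_identical_on_different_chromosomes_both_kept(self):
        panel = make_panel([[0, 0], [1, 1], [2, 2], [0, 0]])
        mmap = make_map(
            {"M0": ("chr1", 1_000), "M1": ("chr2", 1_000)},
            {"chr1": 100_000, "chr2": 100_000},
        )
        out = prune_spacing_ld(panel, mmap)
        assert out.marker_ids == ["M0", "M1"]

    def test_unmapped_marker_fatal(self):
        panel = make_panel([[0, 0], [1, 2], [2, 0]])
        mmap = make_map({"M0": ("chr1", 1_000)}, {"chr1": 100_000})
        with pytest.raises(ValueError, match="M1"):
            prune_spacing_ld(panel, mmap)

    def test_idempotent_on_random_panel(self):
        rng = np.random.default_rng(11)
        n, m = 8, 60
        panel = make_panel(rng.integers(0, 3, size=(n, m)))
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=m, replace=False))
        mmap = make_map(
            {f"M{k}": ("chr1" if k % 2 else "chr2", int(pos[k])) for k in range(m)},
            {"chr1": 2_000_000, "chr2": 2_000_000},
        )
        once = prune_spacing_ld(panel, mmap, window=10)
        twice = prune_spacing_ld(once, mmap, window=10)
        assert twice.marker_ids == once.marker_ids
        np.testing.assert_array_equal(twice.dosages, once.dosages)


class TestExportCervus:
    def make_offspring(self, panel):
        return OffspringSet(
            offspring_ids=["o1", "o2"],
            true_father=["I0", "I1"],
            marker_ids=panel.marker_ids,
            dosages=np.array([[0.0, 1.0], [1.0, np.nan]]),
        )

    def test_allele_coding(self, tmp_path):
        panel = make_panel([[1, 0], [2, None]])
        sol = MarkerSolution(selected=["M0", "M1"], f=2, g=None, depth=0.0,
                             feasible=True, h_used=8)
        paths = export_cervus(panel, self.make_offspring(panel), sol, tmp_path)
        parents = pd.read_csv(paths["parents"], dtype=str)
        assert list(parents.columns) == ["ID", "M0a", "M0b", "M1a", "M1b"]
        mother = parents.iloc[0]
        assert mother["ID"] == "MOTHER" and mother["M0a"] == "A" and mother["M0b"] == "A"
        i0 = parents.iloc[1]
        assert (i0["M0a"], i0["M0b"]) == ("A", "B")
        i1 = parents.iloc[2]
        assert (i1["M0a"], i1["M0b"]) == ("B", "B")
        assert (i1["M1a"], i1["M1b"]) == ("*", "*")

    def test_column_and_row_arithmetic(self, tmp_path):
        rng = np.random.default_rng(3)
        n, m = 30, 34
        panel = make_panel(rng.integers(0, 3, size=(n, m)))
        sol = MarkerSolution(selected=list(panel.marker_ids), f=m, g=None,
                             depth=0.0, feasible=True, h_used=8)
        off = OffspringSet(
            offspring_ids=["o"], true_father=["I0"], marker_ids=panel.marker_ids,
            dosages=rng.integers(0, 2, size=(1, m)).astype(float),
        )
        paths = export_cervus(panel, off, sol, tmp_path)
        parents = pd.read_csv(paths["parents"])
        assert parents.shape == (n + 1, 1 + 2 * m)  # mother + fathers
        fathers = paths["father_list"].read_text().split()
        assert fathers == panel.individual_ids

    def test_empty_solution_fatal(self, tmp_path):
        panel = make_panel([[1, 0], [2, 0]])
        sol = MarkerSolution(selected=[], f=0, g=None, depth=0.0, feasible=False, h_used=8)
        with pytest.raises(ValueError, match="empty"):
            export_cervus(panel, self.make_offspring(panel), sol, tmp_path)
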