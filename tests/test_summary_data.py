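"""File I/O and domain-type invariants for GWAS summary data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ketomr.summary_data import (
    ConfigurationError,
    DataError,
    GWASDataset,
    LDMatrix,
    derive_pvalue,
    read_gene_annotation,
    read_gwas_table,
    read_ld_matrix,
    read_trait_catalogue,
    write_gwas_table,
    write_ld_matrix,
)

from conftest import make_assoc


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


GWAS_HEADER = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
               "eaf", "beta", "se", "pval", "n"]


class TestDerivePvalue:
    @pytest.mark.parametrize(
        "beta, se, expected",
        [
            (0.0, 1.0, 1.0),
            (1.959964, 1.0, 0.05),  # inverse-normal oracle: Phi^-1(0.975)
            (0.1, 0.05, 0.04550026),  # 2*Phi(-2)
            (-0.1, 0.05, 0.04550026),  # two-sided: sign-free
        ],
    )
    def test_wald_p(self, beta, se, expected):
        assert derive_pvalue(beta, se) == pytest.approx(expected, rel=1e-6)

    def test_extreme_z_clips_to_positive(self):
        p = derive_pvalue(100.0, 1.0)
        assert p > 0.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            derive_pvalue(0.1, 0.0)

    @given(
        z1=st.floats(0.01, 30),
        z2=st.floats(0.01, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_abs_z(self, z1, z2):
        if abs(z1 - z2) < 1e-9:
            return
        lo, hi = sorted([z1, z2])
        assert derive_pvalue(hi, 1.0) < derive_pvalue(lo, 1.0)


class TestReadGwasTable:
    def test_identity_read(self, tmp_path):
        path = tmp_path / "g.tsv"
        write_tsv(path, GWAS_HEADER, [
            ["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-8, 1000],
            ["rs2", "1", 200, "C", "T", 0.4, -0.2, 0.02, 1e-10, 1000],
        ])
        ds, diags = read_gwas_table(path, trait_name="x")
        assert len(ds) == 2 and not diags
        assert ds["rs2"].beta == -0.2
        assert ds["rs2"].effect_allele == "C"

    def test_bad_se_row_rejected_with_diagnostic(self, tmp_path):
        path = tmp_path / "g.tsv"
        write_tsv(path, GWAS_HEADER, [
            ["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.0, 1e-8, 1000],
            ["rs2", "1", 200, "C", "T", 0.4, -0.2, 0.02, 1e-10, 1000],
        ])
        ds, diags = read_gwas_table(path)
        assert "rs1" not in ds and "rs2" in ds
        assert len(diags) == 1 and "row 1" in diags[0]

    def test_strict_mode_escalates(self, tmp_path):
        path = tmp_path / "g.tsv"
        write_tsv(path, GWAS_HEADER, [
            ["rs1", "1", 100, "A", "A", 0.3, 0.1, 0.01, 1e-8, 1000],
        ])
        with pytest.raises(DataError):
            read_gwas_table(path, strict=True)

    def test_missing_pval_derived_from_beta_se(self, tmp_path):
        path = tmp_path / "g.tsv"
        cols = [c for c in GWAS_HEADER if c != "pval"]
        write_tsv(path, cols, [["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 1000]])
        cmap = {c: c for c in cols}
        ds, _ = read_gwas_table(path, column_map=cmap)
        assert ds["rs1"].pval == pytest.approx(0.0455, abs=1e-4)

    def test_missing_se_derived_from_beta_pval(self, tmp_path):
        path = tmp_path / "g.tsv"
        cols = [c for c in GWAS_HEADER if c != "se"]
        write_tsv(path, cols, [["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.0455, 1000]])
        ds, _ = read_gwas_table(path, column_map={c: c for c in cols})
        assert ds["rs1"].se == pytest.approx(0.05, rel=1e-3)

    def test_missing_required_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "g.tsv"
        write_tsv(path, ["id"], [["rs1"]])
        with pytest.raises(ConfigurationError):
            read_gwas_table(path, column_map={"variant_id": "id"})

    def test_duplicate_variant_id_names_the_id(self, tmp_path):
        path = tmp_path / "g.tsv"
        write_tsv(path, GWAS_HEADER, [
            ["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-8, 1000],
            ["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-8, 1000],
        ])
        with pytest.raises(DataError, match="rs1"):
            read_gwas_table(path)

    def test_column_renaming(self, tmp_path):
        path = tmp_path / "g.tsv"
        write_tsv(path, ["SNP", "CHR", "BP", "A1", "A2", "FRQ", "BETA", "SE", "P", "N"], [
            ["rs1", "1", 100, "a", "g", 0.3, 0.1, 0.01, 1e-8, 1000],
        ])
        cmap = dict(zip(
            ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
             "eaf", "beta", "se", "pval", "n"],
            ["SNP", "CHR", "BP", "A1", "A2", "FRQ", "BETA", "SE", "P", "N"],
        ))
        ds, _ = read_gwas_table(path, column_map=cmap)
        assert ds["rs1"].effect_allele == "A"  # upper-cased on read

    def test_gzip_transparent(self, tmp_path):
        import gzip

        path = tmp_path / "g.tsv.gz"
        body = "\t".join(GWAS_HEADER) + "\nrs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-8\t1000\n"
        with gzip.open(path, "wt") as fh:
            fh.write(body)
        ds, _ = read_gwas_table(path)
        assert len(ds) == 1

    def test_round_trip_bit_for_bit(self, tmp_path, rng):
        assocs = [
            make_assoc(
                f"rs{i}",
                pos=100 + i,
                beta=float(rng.normal()),
                se=float(rng.uniform(0.001, 1)),
                eaf=float(rng.uniform(0.01, 0.99)),
            )
            for i in range(20)
        ]
        ds = GWASDataset("t", assocs)
        path = tmp_path / "rt.tsv"
        write_gwas_table(ds, path)
        ds2, _ = read_gwas_table(path, trait_name="t")
        for a, b in zip(ds, ds2):
            assert a.variant_id == b.variant_id
            assert a.pos == b.pos
            assert (a.effect_allele, a.other_allele) == (b.effect_allele, b.other_allele)
            assert a.beta == pytest.approx(b.beta, abs=1e-12)
            assert a.se == pytest.approx(b.se, abs=1e-12)
            assert a.eaf == pytest.approx(b.eaf, abs=1e-12)

    def test_rereading_is_deterministic(self, tmp_path):
        path = tmp_path / "g.tsv"
        write_tsv(path, GWAS_HEADER, [
            ["rs%d" % i, "1", 100 + i, "A", "G", 0.3, 0.1, 0.01, 1e-8, 1000]
            for i in range(10)
        ])
        a, _ = read_gwas_table(path)
        b, _ = read_gwas_table(path)
        assert a.variant_ids == b.variant_ids
        assert [x.beta for x in a] == [x.beta for x in b]


class TestGeneAnnotation:
    def test_bed_is_converted_to_one_based(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr5\t0\t100\tOXCT1\n")
        genes = read_gene_annotation(path)
        assert genes[0].start == 1 and genes[0].end == 100

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("")
        assert read_gene_annotation(path) == []

    def test_overlapping_genes_retained(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t0\t100\tGENE1\nchr1\t50\t150\tGENE2\n")
        assert len(read_gene_annotation(path)) == 2

    def test_inverted_interval_rejected(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t100\t50\tGENE1\n")
        with pytest.raises(DataError):
            read_gene_annotation(path)


class TestLDMatrix:
    def test_identity_round_trip(self, tmp_path):
        ld = LDMatrix(["rs1", "rs2"], np.eye(2))
        assert ld.r2_between("rs1", "rs2") == 0.0
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        ld2 = read_ld_matrix(path)
        assert ld2.variant_ids == ["rs1", "rs2"]
        np.testing.assert_allclose(ld2.r, np.eye(2))

    def test_entry_beyond_one_rejected(self):
        with pytest.raises(DataError):
            LDMatrix(["a", "b"], np.array([[1.0, 1.2], [1.2, 1.0]]))

    def test_tiny_asymmetry_symmetrized(self):
        r = np.array([[1.0, 0.5 + 1e-10], [0.5, 1.0]])
        ld = LDMatrix(["a", "b"], r)
        assert ld.r_between("a", "b") == ld.r_between("b", "a")

    def test_large_asymmetry_rejected(self):
        r = np.array([[1.0, 0.6], [0.2, 1.0]])
        with pytest.raises(DataError):
            LDMatrix(["a", "b"], r)

    def test_non_square_rejected(self, tmp_path):
        with pytest.raises(DataError):
            LDMatrix(["a", "b"], np.ones((2, 3)))


def test_catalogue_reader_and_lookup(tmp_path):
    path = tmp_path / "cat.tsv"
    path.write_text(
        "variant_id\tgene_symbol\ttrait\tpval\n"
        "rs1\tSLC2A4\tsystolic blood pressure\t1e-12\n"
        "rs9\tOXCT1\tserum metabolite levels\t1e-3\n"
    )
    cat = read_trait_catalogue(path)
    hits = cat.lookup(gene_symbol="slc2a4", p_max=5e-8)
    assert [h.trait_name for h in hits] == ["systolic blood pressure"]
    assert cat.lookup(variant_ids=["rs9"]) and not cat.lookup(variant_ids=["rs9"], p_max=5e-8)
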