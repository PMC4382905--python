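"""Genome-scan driver: mapping, LD, residual correlations, end-to-end."""

import numpy as np
import pandas as pd
import pytest

from mgas.corr_model import PhenotypeCorrelation, SnpCorrelation
from mgas.genescan import (ScanConfig, ld_from_genotypes, map_snps_to_genes,
                           phenotype_corr, read_annotation, read_pvalue_file,
                           run_scan, write_results)


def snp_frame(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP"])


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["GENE", "CHR", "START", "END"])


class TestMapping:
    def test_extension_boundary_inclusive(self):
        genes = gene_frame([("G1", "1", 1000, 2000)])
        snps = snp_frame([("rs_in", "1", 6999), ("rs_out", "1", 7001),
                          ("rs_left", "1", 1), ("rs_other", "2", 1500)])
        pairs = map_snps_to_genes(snps, genes, extension=5000)
        assert set(pairs["SNP"]) == {"rs_in", "rs_left"}
        # rs_left: 1 >= 1000 - 5000

    def test_overlapping_genes_get_shared_snp(self):
        genes = gene_frame([("G1", "1", 1000, 2000), ("G2", "1", 1500, 3000)])
        snps = snp_frame([("rs1", "1", 1800)])
        pairs = map_snps_to_genes(snps, genes, extension=0)
        assert set(pairs["GENE"]) == {"G1", "G2"}

    def test_chromosome_prefix_normalised_with_warning(self):
        genes = gene_frame([("G1", "chr1", 1000, 2000)])
        snps = snp_frame([("rs1", "1", 1500)])
        with pytest.warns(UserWarning, match="chr"):
            pairs = map_snps_to_genes(snps, genes, extension=0)
        assert len(pairs) == 1


class TestLdFromGenotypes:
    def test_duplicated_column_r_one(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 100).astype(float)
        omega = ld_from_genotypes(np.column_stack([g, g]), ("a", "b"))
        assert omega.values[0, 1] == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, (10000, 4)).astype(float)
        omega = ld_from_genotypes(G, list("abcd"))
        off = omega.values[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_block_r_recovered(self):
        from mgas.simgen import simulate_genotypes, small_gene
        G = simulate_genotypes(20000, small_gene(1), 2)
        omega = ld_from_genotypes(G, [f"s{i}" for i in range(10)])
        off = omega.values[~np.eye(10, dtype=bool)]
        assert np.abs(off - 0.9).max() <= 0.03

    def test_monomorphic_flagged(self):
        rng = np.random.default_rng(3)
        G = np.column_stack([rng.integers(0, 3, 50).astype(float),
                             np.zeros(50)])
        with pytest.warns(UserWarning, match="monomorphic"):
            omega = ld_from_genotypes(G, ("a", "mono"))
        assert omega.values[0, 1] == 0.0
        assert omega.values[1, 1] == 1.0

    def test_pairwise_complete_over_missing(self):
        rng = np.random.default_rng(4)
        G = rng.integers(0, 3, (500, 2)).astype(float)
        G[:50, 0] = np.nan
        omega = ld_from_genotypes(G, ("a", "b"))
        assert np.isfinite(omega.values).all()


class TestPhenotypeCorr:
    def test_no_covariates_is_plain_correlation(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((200, 3))
        got = phenotype_corr(Y)
        np.testing.assert_allclose(got.values,
                                   np.corrcoef(Y, rowvar=False), atol=1e-12)

    def test_covariate_equal_to_phenotype_degenerates(self):
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((100, 2))
        with pytest.warns(UserWarning, match="residual variance"):
            got = phenotype_corr(Y, covariates=Y[:, [0]])
        assert got.values[0, 1] == 0.0

    def test_known_structure_recovered_after_residualising(self):
        rng = np.random.default_rng(17)
        n = 5000
        cov = rng.standard_normal((n, 1))
        target = np.array([[1.0, 0.4], [0.4, 1.0]])
        z = rng.standard_normal((n, 2)) @ np.linalg.cholesky(target).T
        Y = z + cov @ np.array([[0.8, -0.5]])
        got = phenotype_corr(Y, covariates=cov)
        assert got.values[0, 1] == pytest.approx(0.4, abs=0.03)


def write_scan_inputs(tmp_path, pvalue_tables, genes):
    tmp_path.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, rows in pvalue_tables.items():
        df = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "P"])
        p = tmp_path / f"{label}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[label] = p
    gpath = tmp_path / "genes.tsv"
    gene_frame(genes).to_csv(gpath, sep="\t", index=False)
    return paths, gpath


class TestRunScan:
    def test_single_gene_single_snp_passthrough(self, tmp_path):
        paths, gpath = write_scan_inputs(
            tmp_path, {"y1": [("rs1", "1", 1500, 0.0321)]},
            [("G1", "1", 1000, 2000)])
        frames = {"y1": read_pvalue_file(paths["y1"], "y1")}
        sigma = PhenotypeCorrelation(("y1",), np.eye(1))
        omega = SnpCorrelation(("rs1",), np.eye(1))
        out = run_scan(frames, read_annotation(gpath), sigma, omega)
        assert len(out) == 1
        assert out.loc[0, "P_MGAS"] == pytest.approx(0.0321)
        assert out.loc[0, "TOP_SNP"] == "rs1"

    def test_duplicated_phenotype_collapses(self, tmp_path):
        # the same P-value file twice with Sigma = all-ones must leave
        # the single-SNP gene P unchanged (last weight is exactly 1)
        rows = [("rs1", "1", 1500, 0.0321)]
        paths, gpath = write_scan_inputs(
            tmp_path, {"y1": rows, "y2": rows}, [("G1", "1", 1000, 2000)])
        frames = {k: read_pvalue_file(v, k) for k, v in paths.items()}
        sigma = PhenotypeCorrelation(("y1", "y2"),
                                     np.array([[1.0, 1.0], [1.0, 1.0]]))
        omega = SnpCorrelation(("rs1",), np.eye(1))
        out = run_scan(frames, read_annotation(gpath), sigma, omega)
        assert out.loc[0, "P_MGAS"] == pytest.approx(0.0321, abs=1e-12)

    def test_missing_tests_dropped_and_gene_order_fixed(self, tmp_path):
        paths, gpath = write_scan_inputs(
            tmp_path,
            {"y1": [("rs1", "1", 1500, 0.2), ("rs2", "1", 1600, 0.5)],
             "y2": [("rs1", "1", 1500, 0.7)]},
            [("G2", "1", 5000, 6000), ("G1", "1", 1000, 2000)])
        frames = {k: read_pvalue_file(v, k) for k, v in paths.items()}
        sigma = PhenotypeCorrelation(("y1", "y2"), np.eye(2))
        omega = SnpCorrelation(("rs1", "rs2"), np.eye(2))
        out = run_scan(frames, read_annotation(gpath), sigma, omega,
                       ScanConfig(extension=0))
        assert list(out["GENE"]) == ["G1"]  # G2 has no SNPs -> skipped
        assert out.loc[0, "NTEST"] == 3  # y2/rs2 missing, dropped

    def test_scan_deterministic_output(self, tmp_path):
        rng = np.random.default_rng(8)
        rows = [(f"rs{i}", "1", 1000 + 10 * i, float(p))
                for i, p in enumerate(rng.uniform(0.001, 1, 12))]
        paths, gpath = write_scan_inputs(
            tmp_path, {"y1": rows}, [("G1", "1", 1000, 1200)])
        frames = {"y1": read_pvalue_file(paths["y1"], "y1")}
        sigma = PhenotypeCorrelation(("y1",), np.eye(1))
        omega = SnpCorrelation.equicorrelated(12, 0.2, prefix="rs")
        omega = SnpCorrelation(tuple(f"rs{i}" for i in range(12)),
                               omega.values)
        out1 = run_scan(frames, read_annotation(gpath), sigma, omega)
        out2 = run_scan(frames, read_annotation(gpath), sigma, omega)
        write_results(out1, tmp_path / "a.tsv")
        write_results(out2, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == \
            (tmp_path / "b.tsv").read_bytes()

    def test_null_scan_fdr_rarely_rejects(self, tmp_path):
        # global null, 200 single-SNP genes: BH should almost never
        # reject anything
        rng = np.random.default_rng(9)
        zero_runs = 0
        for run in range(10):
            rows = [(f"rs{i}", "1", 1000 + 1000 * i, float(p))
                    for i, p in enumerate(rng.uniform(size=200))]
            genes = [(f"G{i}", "1", 1000 + 1000 * i, 1000 + 1000 * i)
                     for i in range(200)]
            paths, gpath = write_scan_inputs(tmp_path / str(run),
                                             {"y1": rows}, genes)
            frames = {"y1": read_pvalue_file(paths["y1"], "y1")}
            sigma = PhenotypeCorrelation(("y1",), np.eye(1))
            omega = SnpCorrelation(tuple(f"rs{i}" for i in range(200)),
                                   np.eye(200))
            out = run_scan(frames, read_annotation(gpath), sigma, omega,
                           ScanConfig(extension=0))
            zero_runs += int(out["FDR_SIG"].sum() == 0)
        assert zero_runs >= 9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(extension=-1)
        with pytest.raises(ValueError):
            ScanConfig(fdr_alpha=1.5)


class TestReaders:
    def test_pvalue_file_validation(self, tmp_path):
        p = tmp_path / "bad.tsv"
        pd.DataFrame({"SNP": ["a", "a"], "CHR": ["1", "1"],
                      "BP": [1, 2], "P": [0.1, 0.2]}
                     ).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_pvalue_file(p)

    def test_annotation_validation(self, tmp_path):
        p = tmp_path / "genes.tsv"
        pd.DataFrame({"GENE": ["G"], "CHR": ["1"], "START": [10],
                      "END": [5]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="START"):
            read_annotation(p)


def test_read_dosage_vcf(tmp_path):
    pytest.importorskip("cyvcf2")
    from mgas.genescan import read_dosage_vcf
    vcf = tmp_path / "tiny.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1,length=100000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
        "1\t1500\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t1600\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\n")
    G, labels = read_dosage_vcf(vcf)
    assert labels == ("rs1", "rs2")
    np.testing.assert_allclose(G, [[0, 1], [1, 1], [2, 0]])
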