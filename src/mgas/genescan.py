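"""Genome-scan driver: file I/O, SNP-to-gene mapping, per-gene testing.

Inputs are per-phenotype GWAS summary files (tab- or whitespace-
delimited text with SNP, CHR, BP and P columns), a gene annotation table
(GENE, CHR, START, END; 1-based inclusive), a phenotype correlation
matrix, and an LD source: either genotypes (text dosage matrix or VCF)
or a precomputed SNP correlation matrix.  SNPs are mapped onto genes
with a configurable boundary extension (default 5 kb on both sides); a
SNP inside several overlapping gene regions is assigned to all of them.
Per gene the univariate P-values are combined into one multivariate
gene-based P-value, and the Benjamini-Hochberg step-up controls the
false discovery rate across genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corr_model import PhenotypeCorrelation, SnpCorrelation, read_correlation
from .simes_core import TestPValueSet, bh_fdr, mgas

__all__ = [
    "ScanConfig",
    "read_pvalue_file",
    "read_annotation",
    "read_dosage_text",
    "read_dosage_vcf",
    "map_snps_to_genes",
    "ld_from_genotypes",
    "phenotype_corr",
    "run_scan",
    "write_results",
]

log = logging.getLogger("mgas.genescan")

RESULT_COLUMNS = ["GENE", "CHR", "START", "END", "NSNP", "NTEST", "QE",
                  "TOP_PHENO", "TOP_SNP", "TOP_P", "P_MGAS", "FDR_SIG"]


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings (artifact plumbing, not method parameters)."""

    extension: int = 5000          # gene boundary extension in bp
    fdr_alpha: float = 0.05
    dc_threshold: int = 500        # tests above which divide-and-conquer runs
    dc_cutoff: float = 0.50
    seed: int | None = None

    def __post_init__(self):
        if self.extension < 0:
            raise ValueError("boundary extension must be >= 0")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("FDR alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# readers


def _normalise_chrom(series: pd.Series, what: str) -> pd.Series:
    s = series.astype(str).str.strip()
    has_prefix = s.str.lower().str.startswith("chr")
    if has_prefix.any():
        warnings.warn(f"{what}: stripping 'chr' prefix from chromosome names",
                      stacklevel=3)
        s = s.str.replace(r"(?i)^chr", "", regex=True)
    return s


def read_pvalue_file(path, phenotype: str | None = None,
                     columns=("SNP", "CHR", "BP", "P")) -> pd.DataFrame:
    """Read one per-phenotype GWAS summary file.

    Returns a frame with canonical columns SNP, CHR, BP, P and a
    ``phenotype`` attribute (defaulting to the file stem).
    """
    snp, chrom, bp, p = columns
    df = pd.read_csv(path, sep=r"\s+", dtype={snp: str, chrom: str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = df[[snp, chrom, bp, p]].copy()
    out.columns = ["SNP", "CHR", "BP", "P"]
    out["CHR"] = _normalise_chrom(out["CHR"], str(path))
    if out["SNP"].duplicated().any():
        raise ValueError(f"{path}: duplicate SNP identifiers")
    if (out["BP"] <= 0).any():
        raise ValueError(f"{path}: positions must be positive")
    bad = (out["P"] <= 0) | (out["P"] > 1)
    if (out["P"] <= 0).any():
        warnings.warn(f"{path}: flooring {int((out['P'] <= 0).sum())} "
                      "non-positive P-value(s) at 1e-300", stacklevel=2)
        out.loc[out["P"] <= 0, "P"] = 1e-300
        bad = out["P"] > 1
    if bad.any():
        raise ValueError(f"{path}: P-values outside (0, 1]")
    out.attrs["phenotype"] = phenotype or Path(path).stem
    return out


def read_annotation(path) -> pd.DataFrame:
    """Read the gene annotation table (GENE, CHR, START, END)."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"GENE": str, "CHR": str})
    for c in ("GENE", "CHR", "START", "END"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    if (df["START"] > df["END"]).any():
        raise ValueError(f"{path}: gene START must be <= END")
    df = df.copy()
    df["CHR"] = _normalise_chrom(df["CHR"], str(path))
    return df


def read_dosage_text(path):
    """Read a transposed dosage matrix: one row per SNP, first column the
    SNP id, remaining columns per-sample additive dosages."""
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    labels = tuple(str(i) for i in df.index)
    return df.to_numpy(dtype=float).T, labels


def read_dosage_vcf(path):
    """Read additive dosages from a VCF (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF genotype input requires cyvcf2") from exc
    rows, labels = [], []
    for var in VCF(str(path)):
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3 = hom/het/hom-alt
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0],
                           default=np.nan)
        rows.append(dosage)
        labels.append(var.ID or f"{var.CHROM}:{var.POS}")
    return np.asarray(rows).T, tuple(labels)


# ---------------------------------------------------------------------------
# mapping and correlation construction


def map_snps_to_genes(snps: pd.DataFrame, genes: pd.DataFrame,
                      extension: int = 5000) -> pd.DataFrame:
    """Assign SNPs to genes within [START - ext, END + ext] on the same
    chromosome; a SNP in overlapping regions joins every involved gene.

    ``snps`` needs columns SNP, CHR, BP; ``genes`` needs GENE, CHR,
    START, END.  Returns a (GENE, SNP) pair table.
    """
    pairs = []
    snp_chr = _normalise_chrom(snps["CHR"], "snps")
    gene_chr = _normalise_chrom(genes["CHR"], "genes")
    for chrom, gsub in genes.groupby(gene_chr):
        ssub = snps.loc[snp_chr == chrom]
        if ssub.empty:
            continue
        bp = ssub["BP"].to_numpy()
        for _, row in gsub.iterrows():
            lo = row["START"] - extension
            hi = row["END"] + extension
            hit = (bp >= lo) & (bp <= hi)
            for snp in ssub.loc[hit, "SNP"]:
                pairs.append((row["GENE"], snp))
    return pd.DataFrame(pairs, columns=["GENE", "SNP"])


def ld_from_genotypes(G: np.ndarray, labels, subset=None) -> SnpCorrelation:
    """Pearson LD matrix from additive dosages (pairwise-complete over
    missing values); monomorphic SNPs get zero off-diagonals and a
    warning."""
    G = np.asarray(G, dtype=float)
    labels = list(labels)
    if subset is not None:
        idx = [labels.index(s) for s in subset]
        G = G[:, idx]
        labels = [labels[i] for i in idx]
    if G.shape[0] < 2:
        raise ValueError("need at least 2 samples for LD estimation")
    masked = np.ma.masked_invalid(G)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.ma.corrcoef(masked, rowvar=False)
    corr = np.asarray(corr.filled(np.nan), dtype=float)
    mono = ~np.isfinite(np.diag(corr)) | (np.nanstd(G, axis=0) == 0)
    if mono.any():
        warnings.warn(
            f"monomorphic SNP(s) {[labels[i] for i in np.flatnonzero(mono)]}:"
            " correlation undefined, set to 0", stacklevel=2)
        corr[mono, :] = 0.0
        corr[:, mono] = 0.0
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SnpCorrelation(tuple(labels), corr)


def phenotype_corr(Y: np.ndarray, covariates=None,
                   labels=None) -> PhenotypeCorrelation:
    """Phenotype correlations of covariate residuals.

    Each phenotype is residualised on the covariates (with intercept) by
    least squares and the Pearson correlations of the residuals are
    returned -- the same correction applied in the univariate scans must
    be applied here.  A phenotype whose residual is (numerically)
    constant gets zero correlations and a warning.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    labels = tuple(labels) if labels is not None \
        else tuple(f"pheno{i}" for i in range(m))
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, float)])
        beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
        resid = Y - C @ beta
    else:
        resid = Y - Y.mean(axis=0)
    sd = resid.std(axis=0)
    degenerate = sd < 1e-10 * max(1.0, np.abs(Y).max())
    corr = np.eye(m)
    ok = ~degenerate
    if ok.sum() >= 2:
        corr_ok = np.corrcoef(resid[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = corr_ok
    if degenerate.any():
        warnings.warn(
            f"phenotype(s) {[labels[i] for i in np.flatnonzero(degenerate)]} "
            "have ~zero residual variance; correlations set to 0",
            stacklevel=2)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return PhenotypeCorrelation(labels, corr)


# ---------------------------------------------------------------------------
# the scan


def _assemble_tests(gene_snps, pframes, phenotypes):
    """m x n P-value matrix (NaN = missing test) for one gene."""
    n = len(gene_snps)
    m = len(phenotypes)
    P = np.full((m, n), np.nan)
    for i, ph in enumerate(phenotypes):
        sub = pframes[ph].set_index("SNP")["P"]
        hit = sub.reindex(gene_snps)
        P[i, :] = hit.to_numpy()
    return P


def run_scan(pvalue_frames: dict, annotation: pd.DataFrame,
             sigma: PhenotypeCorrelation, ld_source,
             config: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Per-gene multivariate gene-based scan with FDR control.

    Parameters
    ----------
    pvalue_frames : dict
        phenotype label -> summary frame (as from
        :func:`read_pvalue_file`); labels must match ``sigma``.
    annotation : DataFrame
        GENE, CHR, START, END gene table.
    sigma : PhenotypeCorrelation
        Phenotype correlation matrix (covariate-residual based).
    ld_source : SnpCorrelation or (G, labels) tuple
        Either a precomputed SNP correlation matrix covering every SNP,
        or dosage genotypes from which per-gene LD is computed.
    config : ScanConfig

    Returns
    -------
    DataFrame
        One row per analysable gene, ordered by (CHR, START, GENE), with
        Benjamini-Hochberg significance flags at ``config.fdr_alpha``.
    """
    phenotypes = list(sigma.labels)
    missing = [p for p in phenotypes if p not in pvalue_frames]
    if missing:
        raise ValueError(f"no P-value input for phenotype(s) {missing}")

    # SNP universe: union over files; missing tests are dropped test-wise
    all_snps = pd.concat(
        [pvalue_frames[p][["SNP", "CHR", "BP"]] for p in phenotypes]
    ).drop_duplicates(subset="SNP")
    log.info("scan: %d SNPs across %d phenotype file(s)",
             len(all_snps), len(phenotypes))

    pairs = map_snps_to_genes(all_snps, annotation, config.extension)
    by_gene = pairs.groupby("GENE")["SNP"].apply(list)

    rows = []
    skipped = 0
    annotation = annotation.sort_values(
        ["CHR", "START", "GENE"], kind="stable")
    for _, grow in annotation.iterrows():
        gene = grow["GENE"]
        snps = sorted(by_gene.get(gene, []))
        if not snps:
            skipped += 1
            continue
        P = _assemble_tests(snps, pvalue_frames, phenotypes)
        if np.isnan(P).all():
            skipped += 1
            continue
        if isinstance(ld_source, SnpCorrelation):
            idx = [ld_source.labels.index(s) for s in snps]
            omega = SnpCorrelation(
                tuple(snps), ld_source.values[np.ix_(idx, idx)])
        else:
            G, labels = ld_source
            omega = ld_from_genotypes(G, labels, subset=snps)
        tests = TestPValueSet(P, tuple(phenotypes), tuple(snps))
        res = mgas(tests, sigma, omega, gene=gene,
                   dc_threshold=config.dc_threshold,
                   cutoff=config.dc_cutoff)
        rows.append({
            "GENE": gene, "CHR": grow["CHR"], "START": int(grow["START"]),
            "END": int(grow["END"]), "NSNP": len(snps),
            "NTEST": int(tests.present_mask.sum()), "QE": res.q_e,
            "TOP_PHENO": res.top_test[0], "TOP_SNP": res.top_test[1],
            "TOP_P": res.top_test[2], "P_MGAS": res.p_value,
        })
    if skipped:
        log.info("scan: %d gene(s) without mapped SNPs skipped", skipped)
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows)
    reject, threshold = bh_fdr(out["P_MGAS"].to_numpy(), config.fdr_alpha)
    out["FDR_SIG"] = reject
    out.attrs["fdr_threshold"] = threshold
    return out.reset_index(drop=True)


def write_results(results: pd.DataFrame, path) -> None:
    """Write the gene table as tab-delimited text."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
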