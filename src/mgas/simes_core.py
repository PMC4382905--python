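"""The multivariate gene-based extended Simes test.

Given the m x n matrix of univariate SNP-phenotype P-values for one gene
and the expected correlation matrix Phi among those tests, the gene-level
P-value is

    P_gene = min_j ( q_e * p_(j) / q_ej ),   capped at 1,

over the ascendingly ordered P-values p_(1) <= ... <= p_(T).  With a
single phenotype this is the univariate GATES test; with uncorrelated
tests it reduces to the classical Simes combination.  Because every
weight q_e / q_ej >= 1, the scan can stop as soon as the running minimum
is <= the next ordered P-value: no later weighted value can undercut it.

A divide-and-conquer variant clusters the tests on Phi (single linkage
at a correlation cutoff, default 0.50), combines each block separately,
and combines the block P-values with a second extended Simes pass using
the correlations between each block's key test (the test attaining the
block minimum).  This avoids eigendecompositions of very large matrices
for genes with many SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .corr_model import (PhenotypeCorrelation, SnpCorrelation,
                         build_test_correlation)
from .effnum import EIG_TOL, effective_number

__all__ = [
    "TestPValueSet",
    "GeneResult",
    "BlockPartition",
    "extended_simes",
    "simes_rejects",
    "mgas",
    "gates",
    "partition_blocks",
    "mgas_divide_conquer",
    "bh_fdr",
]

#: P-values of exactly 0 (underflow in upstream GWAS output) are floored
#: here so that log-scale comparisons and the (0, 1] domain stay valid.
P_FLOOR = 1e-300

#: Default test count above which :func:`mgas` switches to the
#: divide-and-conquer path.
DC_THRESHOLD = 500


@dataclass(frozen=True)
class TestPValueSet:
    """The m x n univariate P-values for one gene.

    ``pvalues[p, s]`` is the P-value of phenotype p against SNP s; NaN
    marks a missing test (SNP typed but no P-value for that phenotype),
    which is dropped test-wise with the matching Phi rows/columns.
    """

    __test__ = False  # not a pytest collection target

    pvalues: np.ndarray = field(repr=False)
    phenotype_labels: tuple = ()
    snp_labels: tuple = ()

    def __post_init__(self):
        pv = np.array(self.pvalues, dtype=float, ndmin=2)
        if pv.ndim != 2:
            raise ValueError("pvalues must be a 2-D (phenotype x SNP) array")
        present = ~np.isnan(pv)
        if not present.any():
            raise ValueError("no P-values present")
        vals = pv[present]
        if np.any(vals > 1.0) or np.any(vals < 0.0):
            raise ValueError("P-values must lie in (0, 1]")
        if np.any(vals == 0.0):
            warnings.warn(
                f"P-values of exactly 0 floored at {P_FLOOR:g}", stacklevel=2
            )
            pv = np.where(pv == 0.0, P_FLOOR, pv)
        object.__setattr__(self, "pvalues", pv)
        m, n = pv.shape
        phen = self.phenotype_labels or tuple(f"pheno{i}" for i in range(m))
        snps = self.snp_labels or tuple(f"snp{i}" for i in range(n))
        if len(phen) != m or len(snps) != n:
            raise ValueError("label counts do not match P-value matrix shape")
        object.__setattr__(self, "phenotype_labels", tuple(phen))
        object.__setattr__(self, "snp_labels", tuple(snps))

    @property
    def m(self) -> int:
        return self.pvalues.shape[0]

    @property
    def n(self) -> int:
        return self.pvalues.shape[1]

    @property
    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.pvalues)


@dataclass(frozen=True)
class GeneResult:
    """Gene-level combination result."""

    gene: str
    n_snps: int
    m_phenotypes: int
    p_value: float
    q_e: float
    top_test: tuple  # (phenotype label, SNP label, raw P of the top test)
    method: str = "MGAS"

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("gene-level P-value must lie in (0, 1]")


@dataclass(frozen=True)
class BlockPartition:
    """Cluster assignment of tests and the per-block key test."""

    labels: np.ndarray = field(repr=False)  # block id per test
    key_tests: dict = field(default_factory=dict)  # block id -> test index

    @property
    def n_blocks(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, block: int) -> np.ndarray:
        return np.flatnonzero(self.labels == block)


def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty P-value sequence")
    if np.any(pvals <= 0.0) or np.any(pvals > 1.0):
        raise ValueError("P-values must lie in (0, 1]")
    return pvals


def _simes_scan(ps: np.ndarray, phi: np.ndarray, early_stop: bool = True):
    """Core weighted-minimum scan over ascending P-values.

    Returns ``(p_combined, argmin_rank)`` where ``argmin_rank`` is the
    0-based rank of the ordered test attaining the minimum weighted
    P-value.
    """
    t = ps.size
    if phi.shape != (t, t):
        raise ValueError("Phi shape does not match the P-value count")
    if np.any(np.diff(ps) < 0):
        raise ValueError("P-values must be in ascending order")
    q_e = effective_number(phi)
    w_min = np.inf
    argmin = 0
    for j in range(1, t + 1):
        q_ej = effective_number(phi[:j, :j])
        weighted = max(q_e / q_ej, 1.0) * ps[j - 1]
        if weighted < w_min:
            w_min = weighted
            argmin = j - 1
        if early_stop and j < t and w_min <= ps[j]:
            break
    return min(w_min, 1.0), argmin, q_e


def extended_simes(pvals, phi, early_stop: bool = True) -> float:
    """Combine ascendingly ordered P-values with effective-number weights.

    Parameters
    ----------
    pvals : sequence of float
        Ascending P-values in (0, 1].
    phi : array-like or TestCorrelation
        Test correlation matrix ordered consistently with ``pvals``.
    early_stop : bool
        Stop the scan once the running minimum cannot be undercut
        (identical result, fewer eigendecompositions).

    Returns
    -------
    float
        ``min_j q_e p_(j) / q_ej`` capped at 1.
    """
    ps = _check_pvals(pvals)
    mat = phi.values if hasattr(phi, "values") else np.asarray(phi, float)
    p, _, _ = _simes_scan(ps, mat, early_stop=early_stop)
    return p


def simes_rejects(pvals, phi, alpha: float) -> bool:
    """Exact significance indicator ``extended_simes(...) <= alpha``.

    Because every weight is >= 1, a rank j can only produce a weighted
    value <= alpha if its raw P-value is <= alpha; ranks beyond that
    point need no eigendecomposition.  Used by the simulation harness
    where only rejection counts are needed.
    """
    ps = _check_pvals(pvals)
    mat = phi.values if hasattr(phi, "values") else np.asarray(phi, float)
    if np.any(np.diff(ps) < 0):
        raise ValueError("P-values must be in ascending order")
    k = int(np.searchsorted(ps, alpha, side="right"))
    if k == 0:
        return False
    q_e = effective_number(mat)
    for j in range(1, k + 1):
        q_ej = effective_number(mat[:j, :j])
        if max(q_e / q_ej, 1.0) * ps[j - 1] <= alpha:
            return True
    return False


def _order_present(tests: TestPValueSet):
    """Ascending order of present tests; ties broken by phenotype-major
    test index (stable sort) for cross-platform determinism."""
    flat = tests.pvalues.ravel()
    present = np.flatnonzero(~np.isnan(flat))
    order = present[np.argsort(flat[present], kind="stable")]
    return order, flat


def mgas(tests: TestPValueSet, sigma: PhenotypeCorrelation,
         omega: SnpCorrelation, gene: str = "",
         divide_conquer: bool | None = None,
         dc_threshold: int = DC_THRESHOLD,
         cutoff: float = 0.50) -> GeneResult:
    """Multivariate gene-based P-value for one gene.

    Builds Phi from Sigma and Omega, orders the present P-values
    ascendingly and applies the extended Simes combination.  When
    ``divide_conquer`` is None the divide-and-conquer path engages
    automatically for more than ``dc_threshold`` present tests.
    """
    if tests.m != sigma.m:
        raise ValueError("phenotype count does not match Sigma")
    if tests.n != omega.n:
        raise ValueError("SNP count does not match Omega")
    n_present = int(tests.present_mask.sum())
    if divide_conquer is None:
        divide_conquer = n_present > dc_threshold
    if divide_conquer:
        return mgas_divide_conquer(tests, sigma, omega, gene=gene,
                                   cutoff=cutoff)
    phi = build_test_correlation(sigma, omega).values
    order, flat = _order_present(tests)
    ps = flat[order]
    sub = phi[np.ix_(order, order)]
    p, argmin, q_e = _simes_scan(ps, sub)
    top = order[argmin]
    top_label = (tests.phenotype_labels[top // tests.n],
                 tests.snp_labels[top % tests.n],
                 float(flat[top]))
    return GeneResult(gene=gene, n_snps=tests.n, m_phenotypes=tests.m,
                      p_value=p, q_e=q_e, top_test=top_label, method="MGAS")


def gates(pvals, omega: SnpCorrelation, gene: str = "") -> float:
    """Univariate gene-based test: the single-phenotype special case."""
    ps = np.atleast_1d(np.asarray(pvals, dtype=float))
    tests = TestPValueSet(ps[None, :], ("pheno",), omega.labels)
    sigma = PhenotypeCorrelation(("pheno",), np.eye(1))
    return mgas(tests, sigma, omega, gene=gene, divide_conquer=False).p_value


def partition_blocks(phi, cutoff: float = 0.50) -> BlockPartition:
    """Single-linkage clusters of tests with expected correlation >= cutoff.

    Implemented as connected components of the thresholded correlation
    graph, which is exactly single-linkage clustering cut at ``cutoff``.
    Deterministic given Phi: components are relabelled by their smallest
    member index.
    """
    mat = phi.values if hasattr(phi, "values") else np.asarray(phi, float)
    adj = csr_matrix(np.abs(mat) >= cutoff)
    _, raw = connected_components(adj, directed=False)
    # relabel components in order of first appearance
    _, labels = np.unique(raw, return_inverse=True)
    first = {}
    for idx, lab in enumerate(labels):
        first.setdefault(int(lab), idx)
    rank = {lab: i for i, (lab, _) in
            enumerate(sorted(first.items(), key=lambda kv: kv[1]))}
    relabelled = np.array([rank[int(l)] for l in labels])
    return BlockPartition(labels=relabelled)


def mgas_divide_conquer(tests: TestPValueSet, sigma: PhenotypeCorrelation,
                        omega: SnpCorrelation, gene: str = "",
                        cutoff: float = 0.50) -> GeneResult:
    """Blockwise extended Simes with a second pass over block P-values.

    Tests are clustered on Phi at ``cutoff``; each block is combined by
    the extended Simes test with its within-block Phi submatrix, the test
    attaining the block minimum becomes the block's key test, and the
    block P-values are combined by the extended Simes test again using
    the Phi submatrix of the key tests.  The reported q_e is the sum of
    the blockwise effective numbers (the full-matrix q_e is exactly what
    this algorithm avoids computing).
    """
    if tests.m != sigma.m:
        raise ValueError("phenotype count does not match Sigma")
    if tests.n != omega.n:
        raise ValueError("SNP count does not match Omega")
    phi = build_test_correlation(sigma, omega).values
    order, flat = _order_present(tests)
    ps = flat[order]
    sub = phi[np.ix_(order, order)]

    part = partition_blocks(sub, cutoff=cutoff)
    block_ps = []
    key_rows = []  # index into `order` of each block's key test
    q_e_total = 0.0
    for b in range(part.n_blocks):
        rows = part.members(b)  # ascending rank order within block
        bp, argmin, bqe = _simes_scan(ps[rows], sub[np.ix_(rows, rows)])
        block_ps.append(min(bp, 1.0))
        key_rows.append(rows[argmin])
        q_e_total += bqe
    block_ps = np.clip(np.asarray(block_ps), P_FLOOR, 1.0)
    key_rows = np.asarray(key_rows)
    border = np.argsort(block_ps, kind="stable")
    keys = key_rows[border]
    p, _, _ = _simes_scan(block_ps[border], sub[np.ix_(keys, keys)])
    # top test: key test of the block that wins the second pass
    top = order[key_rows[np.argmin(block_ps)]]
    top_label = (tests.phenotype_labels[top // tests.n],
                 tests.snp_labels[top % tests.n],
                 float(flat[top]))
    return GeneResult(gene=gene, n_snps=tests.n, m_phenotypes=tests.m,
                      p_value=min(p, 1.0), q_e=q_e_total,
                      top_test=top_label, method="MGAS-DC")


def bh_fdr(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg step-up over gene-level P-values.

    Returns
    -------
    (ndarray of bool, float)
        Rejection flags in input order and the realised P-value
        threshold (largest rejected P, or 0.0 when nothing is rejected).
    """
    ps = _check_pvals(pvals)
    reject, _, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    threshold = float(ps[reject].max()) if reject.any() else 0.0
    return reject, threshold
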