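"""Expected correlations among association P-values.

The gene-level combination step needs the correlation matrix Phi of the
m*n univariate SNP-phenotype P-values for one gene.  Phi is not observed,
but under the null hypothesis it is well approximated by a fixed
sixth-order polynomial applied elementwise to the Kronecker product of
the phenotype correlation matrix Sigma (m x m) and the SNP (LD)
correlation matrix Omega (n x n).  The polynomial was calibrated by
simulation (see :mod:`mgas.calibration` for the replication of that
calibration) and is frozen here as a production constant.

Test-ordering convention (shared by every module): the m*n tests are
indexed phenotype-major, ``t = phenotype_index * n + snp_index``, which is
exactly the row-major raveling of the m x n P-value matrix and the native
index order of ``numpy.kron(sigma, omega)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PVALUE_CORR_COEFFS",
    "pvalue_corr_poly",
    "PhenotypeCorrelation",
    "SnpCorrelation",
    "TestCorrelation",
    "build_test_correlation",
    "read_correlation",
    "write_correlation",
]

#: Coefficients of the P-value correlation polynomial, highest order first
#: (degree 6, no constant term so that independent tests map to 0).
PVALUE_CORR_COEFFS = np.array(
    [0.3867, 0.0021, -0.1347, -0.0104, 0.7276, 0.0068, 0.0]
)

_SYM_TOL = 1e-8


def pvalue_corr_poly(x):
    """Map a product of phenotype and SNP correlations to the expected
    correlation between the two association P-values.

    Parameters
    ----------
    x : float or array-like
        Entry (or entries) of the Kronecker product Sigma (x) Omega;
        every value must lie in [-1, 1].

    Returns
    -------
    float or ndarray
        ``0.3867 x^6 + 0.0021 x^5 - 0.1347 x^4 - 0.0104 x^3 + 0.7276 x^2
        + 0.0068 x`` clamped to [0, 1].  P-values of two null tests are
        nonnegatively correlated, hence the lower clamp; the upper clamp
        guards the polynomial's slight overshoot near |x| = 1.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlation products must lie in [-1, 1]")
    out = np.clip(np.polyval(PVALUE_CORR_COEFFS, arr), 0.0, 1.0)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def _validate_correlation(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{what} matrix must be square, got {values.shape}")
    if values.shape[0] < 1:
        raise ValueError(f"{what} matrix must be at least 1 x 1")
    if not np.allclose(values, values.T, atol=_SYM_TOL):
        raise ValueError(f"{what} matrix must be symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=_SYM_TOL):
        raise ValueError(f"{what} matrix must have unit diagonal")
    if np.any(np.abs(values) > 1.0 + _SYM_TOL):
        raise ValueError(f"{what} entries must lie in [-1, 1]")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return values


@dataclass(frozen=True)
class PhenotypeCorrelation:
    """Phenotype correlation matrix Sigma with phenotype labels."""

    labels: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = _validate_correlation(self.values, "phenotype correlation")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != values.shape[0]:
            raise ValueError("label count does not match matrix dimension")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @classmethod
    def equicorrelated(cls, m: int, rho: float, prefix: str = "pheno"):
        values = np.full((m, m), float(rho))
        np.fill_diagonal(values, 1.0)
        return cls(tuple(f"{prefix}{i}" for i in range(m)), values)


@dataclass(frozen=True)
class SnpCorrelation:
    """SNP (LD) correlation matrix Omega with SNP labels."""

    labels: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = _validate_correlation(self.values, "SNP correlation")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != values.shape[0]:
            raise ValueError("label count does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def equicorrelated(cls, n: int, r: float, prefix: str = "snp"):
        values = np.full((n, n), float(r))
        np.fill_diagonal(values, 1.0)
        return cls(tuple(f"{prefix}{i}" for i in range(n)), values)

    @classmethod
    def block_diagonal(cls, block_sizes: Sequence[int], r_within: float,
                       prefix: str = "snp"):
        """Independent LD blocks, equicorrelated at ``r_within`` inside."""
        n = int(sum(block_sizes))
        values = np.zeros((n, n))
        start = 0
        for size in block_sizes:
            values[start:start + size, start:start + size] = r_within
            start += size
        np.fill_diagonal(values, 1.0)
        return cls(tuple(f"{prefix}{i}" for i in range(n)), values)


@dataclass(frozen=True)
class TestCorrelation:
    """Expected correlation matrix Phi among the m*n test P-values.

    Rows/columns follow the phenotype-major convention
    ``t = phenotype_index * n + snp_index``.  Phi results from an
    elementwise polynomial map and is therefore not guaranteed positive
    semi-definite; downstream eigenvalue sums only use eigenvalues
    exceeding 1, so no PSD repair is applied.
    """

    __test__ = False  # not a pytest collection target

    values: np.ndarray = field(repr=False)
    phenotype_labels: tuple = ()
    snp_labels: tuple = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("test correlation matrix must be square")
        if not np.allclose(values, values.T, atol=_SYM_TOL):
            raise ValueError("test correlation matrix must be symmetric")
        object.__setattr__(self, "values", (values + values.T) / 2.0)
        object.__setattr__(self, "phenotype_labels", tuple(self.phenotype_labels))
        object.__setattr__(self, "snp_labels", tuple(self.snp_labels))

    @property
    def n_tests(self) -> int:
        return self.values.shape[0]

    def test_labels(self) -> list:
        return [
            (p, s) for p in self.phenotype_labels for s in self.snp_labels
        ]


def build_test_correlation(sigma: PhenotypeCorrelation,
                           omega: SnpCorrelation) -> TestCorrelation:
    """Build Phi = f(Sigma (x) Omega) elementwise, diagonal reset to 1.

    The polynomial maps the unit diagonal of the Kronecker product to
    0.9781 rather than 1; the diagonal is reset explicitly so Phi is a
    correlation matrix.  Off-diagonal entries are left exactly as the
    polynomial produced them (the calibration fitted the polynomial as
    is, so renormalising off-diagonals would bias the approximation).
    """
    x = np.kron(sigma.values, omega.values)
    phi = pvalue_corr_poly(x)
    np.fill_diagonal(phi, 1.0)
    return TestCorrelation(phi, sigma.labels, omega.labels)


def read_correlation(path, kind: str = "phenotype"):
    """Read a labelled square correlation matrix from tab-delimited text.

    The expected layout is a header row of labels and one row per label
    (row label in the first column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise ValueError(f"{path}: row and column labels differ")
    cls = PhenotypeCorrelation if kind == "phenotype" else SnpCorrelation
    return cls(labels, df.to_numpy(dtype=float))


def write_correlation(matrix, path) -> None:
    """Write a labelled correlation matrix as tab-delimited text."""
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g")
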