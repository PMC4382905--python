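"""Independent oracles used across the test suite.

These deliberately avoid the package's own code paths: eigenvalues come
from closed forms or the general (non-symmetric) eigensolver, Simes and
step-up procedures are written as direct transcriptions of their
definitions.
"""

import numpy as np


def poly(x):
    """The P-value correlation polynomial, written out longhand."""
    return (0.3867 * x ** 6 + 0.0021 * x ** 5 - 0.1347 * x ** 4
            - 0.0104 * x ** 3 + 0.7276 * x ** 2 + 0.0068 * x)


def equicorr_kron_eigs(m, rho, n, r):
    """Eigenvalues (with multiplicities) of the polynomial-mapped test
    correlation matrix for equicorrelated Sigma(m, rho) and Omega(n, r).

    The matrix is a linear combination of I (x) I, I (x) J, J (x) I and
    J (x) J, so its eigenvalues follow from the eigenvalues {size, 0} of
    the all-ones matrix J.
    """
    a = poly(r)        # same phenotype, different SNPs
    b = poly(rho)      # same SNP, different phenotypes
    c = poly(rho * r)  # both different
    lams = [
        (1 + (n - 1) * a + (m - 1) * b + (m - 1) * (n - 1) * c, 1),
        (1 - a + (m - 1) * b - (m - 1) * c, n - 1),
        (1 + (n - 1) * a - b - (n - 1) * c, m - 1),
        (1 - a - b + c, (m - 1) * (n - 1)),
    ]
    return lams


def effective_number_from_eigs(lams):
    """j - sum over eigenvalues above 1 of (eigenvalue - 1)."""
    j = sum(mult for _, mult in lams)
    excess = sum(mult * (lam - 1.0) for lam, mult in lams if lam > 1.0)
    return j - excess


def qe_equicorr_kron(m, rho, n, r, n_blocks=1):
    """Closed-form q_e for Sigma(m, rho) and a block-diagonal Omega of
    ``n_blocks`` independent equicorrelated blocks of n SNPs each.

    The mapped matrix is block diagonal over SNP blocks (the polynomial
    sends 0 to 0), so the blockwise excesses add.
    """
    lams = equicorr_kron_eigs(m, rho, n, r)
    qe_block = effective_number_from_eigs(lams)
    total = n_blocks * m * n
    return total - n_blocks * (m * n - qe_block)


def prefix_qej_same_phenotype(j, r):
    """q_ej for a prefix of j tests of one phenotype against j
    equicorrelated SNPs: eigenvalues 1 + (j-1)a and 1 - a."""
    a = poly(r)
    return j - max(0.0, (j - 1) * a)


def simes(pvals):
    """Classical Simes combination (independence)."""
    ps = np.sort(np.asarray(pvals, dtype=float))
    k = ps.size
    return min(1.0, float(np.min(k * ps / np.arange(1, k + 1))))


def bh_stepup(pvals, alpha):
    """Benjamini-Hochberg step-up written from the definition."""
    ps = np.asarray(pvals, dtype=float)
    k = ps.size
    order = np.argsort(ps)
    crit = alpha * np.arange(1, k + 1) / k
    below = ps[order] <= crit
    reject = np.zeros(k, dtype=bool)
    if below.any():
        last = int(np.max(np.flatnonzero(below)))
        reject[order[: last + 1]] = True
    return reject


def extended_simes_full(pvals, phi):
    """Unweighted full scan using the general eigensolver, no early stop."""
    ps = np.asarray(pvals, dtype=float)
    t = ps.size

    def qe(mat):
        lam = np.real(np.linalg.eigvals(mat))
        return max(1.0, mat.shape[0] - lam[lam > 1.0].sum()
                   + (lam > 1.0).sum())

    q_all = qe(phi)
    vals = [max(q_all / qe(phi[:j, :j]), 1.0) * ps[j - 1]
            for j in range(1, t + 1)]
    return min(1.0, min(vals))


def random_correlation(dim, rng):
    """Random PSD correlation matrix from normalised Wishart draws."""
    a = rng.standard_normal((dim + 2, dim))
    c = a.T @ a
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c
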