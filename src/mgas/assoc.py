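"""Univariate association engines and comparator gene-based tests.

The univariate tests here produce the P-value inputs for the gene-level
combination: a Wald test for continuous phenotypes (simple linear
regression) and a 1-df likelihood-ratio chi-square for binary phenotypes
(logistic regression).  Four comparator gene-based tests are provided:

* ``gates_sum`` - the 20-phenotype sum score regressed on every SNP,
  combined by the univariate extended Simes test;
* ``multiple_regression_gene`` - the sum score regressed on all SNPs at
  once, overall F-test;
* ``manova_gene`` - all phenotypes on all SNPs, Wilks' lambda with Rao's
  F approximation;
* ``gates_manova`` - one single-SNP MANOVA per SNP, P-values combined by
  the univariate extended Simes test.

Covariates are expected to be handled upstream by residualising the
phenotypes (see :func:`mgas.genescan.phenotype_corr`), mirroring common
GWAS practice of covariate-corrected inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special, stats

from .corr_model import SnpCorrelation
from .simes_core import GeneResult, gates

__all__ = [
    "wald_linear",
    "wald_linear_matrix",
    "chi2_logistic",
    "gates_sum",
    "multiple_regression_gene",
    "manova_gene",
    "gates_manova",
]


# ---------------------------------------------------------------------------
# univariate engines


def wald_linear(y, g) -> float:
    """Two-sided Wald P-value for the slope of y on g.

    For simple linear regression the Wald t statistic for the slope is
    algebraically ``r * sqrt((N-2) / (1-r^2))`` with r the Pearson
    correlation, which is what is computed here.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and g must be 1-D vectors of equal length")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    return float(wald_linear_matrix(y[:, None], g[:, None])[0, 0])


def wald_linear_matrix(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """All m x n slope Wald P-values for phenotype matrix Y (N x m) and
    dosage matrix G (N x n), vectorised through the correlation identity."""
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    n_obs = Y.shape[0]
    if G.shape[0] != n_obs:
        raise ValueError("Y and G must have the same number of rows")
    Gc = G - G.mean(axis=0)
    gss = (Gc ** 2).sum(axis=0)
    if np.any(gss == 0.0):
        raise ValueError("constant genotype column: degenerate predictor")
    Yc = Y - Y.mean(axis=0)
    yss = (Yc ** 2).sum(axis=0)
    r = (Yc.T @ Gc) / np.sqrt(np.outer(yss, gss))
    r = np.clip(r, -1.0, 1.0)
    df = n_obs - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
    return 2.0 * special.stdtr(df, -np.abs(t))


def _logistic_lr(y: np.ndarray, g: np.ndarray, max_iter: int = 50,
                 tol: float = 1e-10):
    """Newton fit of logit(y) ~ 1 + g; returns (LR chi2, converged)."""
    n = y.size
    X = np.column_stack([np.ones(n), g])
    beta = np.zeros(2)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = special.expit(eta)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if abs(ll - ll_prev) < tol and np.abs(step).max() < 1e-6:
            converged = True
            break
        ll_prev = ll
    p1 = y.mean()
    ll0 = float(y.sum() * np.log(p1) + (n - y.sum()) * np.log(1.0 - p1))
    eta = np.clip(X @ beta, -30, 30)
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    lr = max(0.0, 2.0 * (ll - ll0))
    # runaway slope signals (quasi-)separation
    if np.abs(beta[1]) > 15:
        converged = False
    return lr, converged


def chi2_logistic(y, g) -> float:
    """1-df likelihood-ratio chi-square P-value for the dosage slope in
    logistic regression.

    Under (quasi-)separation the MLE diverges; the score test, which
    needs no slope estimate, is then used as a fallback with a warning.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and g must be 1-D vectors of equal length")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("binary phenotype must be coded 0/1")
    if classes.size < 2:
        raise ValueError("both phenotype classes must be present")
    if np.ptp(g) == 0.0:
        raise ValueError("constant genotype column: degenerate predictor")
    lr, converged = _logistic_lr(y, g)
    if not converged:
        warnings.warn("logistic fit did not converge (separation?); "
                      "falling back to the score test", stacklevel=2)
        ybar = y.mean()
        gc = g - g.mean()
        u = float(gc @ (y - ybar))
        v = float(ybar * (1.0 - ybar) * (gc ** 2).sum())
        lr = u * u / v
    return float(stats.chi2.sf(lr, df=1))


# ---------------------------------------------------------------------------
# MANOVA via Wilks' lambda


def _drop_aliased(G: np.ndarray):
    """Drop linearly dependent dosage columns (pivoted-QR rank check)."""
    Gc = G - G.mean(axis=0)
    _, rdiag, piv = _pivoted_qr(Gc)
    tol = max(Gc.shape) * np.finfo(float).eps * (abs(rdiag[0]) or 1.0)
    rank = int((np.abs(rdiag) > tol).sum())
    keep = np.sort(piv[:rank])
    if rank < G.shape[1]:
        warnings.warn(
            f"dropping {G.shape[1] - rank} aliased genotype column(s)",
            stacklevel=3,
        )
    return G[:, keep], keep


def _pivoted_qr(a: np.ndarray):
    from scipy.linalg import qr

    _, r, piv = qr(a, mode="economic", pivoting=True)
    return None, np.diag(r), piv


def wilks_lambda_p(Y: np.ndarray, G: np.ndarray) -> float:
    """P-value for the joint null of all SNP effects on all phenotypes.

    Wilks' lambda ``det(E) / det(E + H)`` from the multivariate linear
    model Y ~ 1 + G, mapped to an F statistic by Rao's approximation
    (exact for one response or one predictor).
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    n_obs, p = Y.shape
    q = G.shape[1]
    if n_obs <= p + q:
        raise ValueError("insufficient sample size for MANOVA "
                         f"(N={n_obs} <= m+n={p + q})")
    Yc = Y - Y.mean(axis=0)
    Gc = G - G.mean(axis=0)
    # E = residual SSCP of the full model, E0 = of the intercept-only model
    beta, *_ = np.linalg.lstsq(Gc, Yc, rcond=None)
    resid = Yc - Gc @ beta
    E = resid.T @ resid
    E0 = Yc.T @ Yc
    sign, logdet_E = np.linalg.slogdet(E)
    if sign <= 0:
        raise ValueError("singular residual SSCP; reduce phenotypes or SNPs")
    _, logdet_E0 = np.linalg.slogdet(E0)
    lam = np.exp(logdet_E - logdet_E0)
    # Rao's F approximation
    v = n_obs - q - 1
    t = 1.0
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    w = v + q - (p + q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f_stat = (1.0 - lam_t) / lam_t * df2 / df1
    return float(stats.f.sf(f_stat, df1, df2))


# ---------------------------------------------------------------------------
# gene-based comparator tests


def gates_sum(Y, G, omega: SnpCorrelation, gene: str = "") -> GeneResult:
    """Sum-score univariate gene test: row-sum of the phenotypes, one
    Wald test per SNP, combined by the univariate extended Simes test."""
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    score = Y.sum(axis=1)
    ps = wald_linear_matrix(score[:, None], G)[0]
    p = gates(ps, omega, gene=gene)
    top = int(np.argmin(ps))
    return GeneResult(gene=gene, n_snps=G.shape[1], m_phenotypes=Y.shape[1],
                      p_value=p, q_e=np.nan,
                      top_test=("sum-score", omega.labels[top], float(ps[top])),
                      method="GATES-sum")


def multiple_regression_gene(Y, G) -> float:
    """Overall F-test of the sum score on all SNPs jointly.

    Rank-deficient genotype matrices have aliased columns dropped (with a
    warning); the numerator degrees of freedom equal the retained rank.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    score = Y.sum(axis=1) if Y.ndim == 2 else Y
    G, _ = _drop_aliased(G)
    n_obs, k = G.shape
    yc = score - score.mean()
    Gc = G - G.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Gc, yc, rcond=None)
    resid = yc - Gc @ beta
    rss = float(resid @ resid)
    tss = float(yc @ yc)
    df2 = n_obs - k - 1
    f_stat = ((tss - rss) / k) / (rss / df2)
    return float(stats.f.sf(f_stat, k, df2))


def manova_gene(Y, G) -> float:
    """MANOVA gene test: all phenotypes on all SNPs, Wilks' lambda."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be an N x m phenotype matrix")
    G = np.asarray(G, dtype=float)
    G, _ = _drop_aliased(G)
    return wilks_lambda_p(Y, G)


def gates_manova(Y, G, omega: SnpCorrelation, gene: str = "") -> GeneResult:
    """Per-SNP multivariate MANOVAs combined by the univariate extended
    Simes test with the SNP LD matrix."""
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    ps = np.array([wilks_lambda_p(Y, G[:, [j]]) for j in range(G.shape[1])])
    p = gates(ps, omega, gene=gene)
    top = int(np.argmin(ps))
    return GeneResult(gene=gene, n_snps=G.shape[1], m_phenotypes=Y.shape[1],
                      p_value=p, q_e=np.nan,
                      top_test=("manova", omega.labels[top], float(ps[top])),
                      method="GATES-MANOVA")
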