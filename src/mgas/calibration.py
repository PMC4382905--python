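"""Replication of the P-value correlation calibration.

The polynomial in :mod:`mgas.corr_model` approximates the correlation
between two null association P-values as a function of the product of
the phenotype correlation rho and the SNP correlation r.  This module
re-derives those correlations by simulation: two correlated bi-allelic
SNPs (Hardy-Weinberg haplotype sampling) and two correlated phenotypes
are drawn for N subjects, the four univariate tests are run, and the
Pearson correlation of the two "cross" P-values -- phenotype 1 x SNP 2
and phenotype 2 x SNP 1, whose correlation is governed by rho*r -- is
estimated over many replicate datasets.

Defaults are desk-scale (grid step 0.1, 2000 replicates per cell); the
full-scale settings (step 0.05, 10 000 replicates) are available through
the function arguments.  Validation reports the coefficient of
determination of the frozen polynomial against the fresh estimates; the
coefficients are never refit into the production constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .corr_model import pvalue_corr_poly

__all__ = [
    "CalibrationCell",
    "haplotype_frequencies",
    "estimate_p_correlation",
    "run_grid",
    "validate_polynomial",
]


def haplotype_frequencies(maf1: float, maf2: float, r: float) -> np.ndarray:
    """Two-SNP haplotype probabilities (AB, Ab, aB, ab) for minor-allele
    frequencies ``maf1``, ``maf2`` and haplotypic correlation ``r``.

    Raises for infeasible combinations (the requested r exceeds the
    Lewontin-type bounds for the given frequencies).
    """
    if not (0.0 < maf1 < 1.0 and 0.0 < maf2 < 1.0):
        raise ValueError("allele frequencies must lie in (0, 1)")
    d = r * np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))
    p11 = maf1 * maf2 + d
    freqs = np.array([
        p11,
        maf1 - p11,
        maf2 - p11,
        1.0 - maf1 - maf2 + p11,
    ])
    if np.any(freqs < -1e-12):
        raise ValueError(
            f"infeasible haplotype frequencies for maf=({maf1}, {maf2}), "
            f"r={r}")
    return np.clip(freqs, 0.0, 1.0)


@dataclass(frozen=True)
class CalibrationCell:
    """One grid cell of the calibration study."""

    rho: float
    r: float
    maf1: float = 0.3
    maf2: float | None = None
    phenotype_type: str = "quantitative"
    n_subjects: int = 4000
    n_reps: int = 2000

    def __post_init__(self):
        if abs(self.rho) > 1.0:
            raise ValueError("|rho| must be <= 1")
        object.__setattr__(self, "maf2",
                           self.maf1 if self.maf2 is None else self.maf2)
        haplotype_frequencies(self.maf1, self.maf2, self.r)  # feasibility
        if self.phenotype_type not in ("quantitative", "binary"):
            raise ValueError("phenotype_type must be quantitative or binary")

    @property
    def x(self) -> float:
        """The product rho*r driving the cross P-value correlation."""
        return self.rho * self.r


def _sample_genotypes(cell: CalibrationCell, rng, chunk: int):
    """(chunk, N) dosage arrays for the two SNPs, haplotype-pair sampled."""
    freqs = haplotype_frequencies(cell.maf1, cell.maf2, cell.r)
    cum = np.cumsum(freqs)
    a1 = np.array([1, 1, 0, 0], dtype=np.int8)
    a2 = np.array([1, 0, 1, 0], dtype=np.int8)
    n = cell.n_subjects
    c1 = np.searchsorted(cum, rng.random((chunk, n)))
    c2 = np.searchsorted(cum, rng.random((chunk, n)))
    g1 = (a1[c1] + a1[c2]).astype(np.float64)
    g2 = (a2[c1] + a2[c2]).astype(np.float64)
    return g1, g2


def _wald_p_rows(y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Row-wise slope Wald P-values for paired (reps, N) arrays."""
    n = y.shape[1]
    yc = y - y.mean(axis=1, keepdims=True)
    gc = g - g.mean(axis=1, keepdims=True)
    denom = np.sqrt((yc ** 2).sum(axis=1) * (gc ** 2).sum(axis=1))
    r = np.clip((yc * gc).sum(axis=1) / denom, -1.0, 1.0)
    t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    return 2.0 * special.stdtr(n - 2, -np.abs(t))


def _logistic_lr_rows(y: np.ndarray, g: np.ndarray,
                      n_iter: int = 8) -> np.ndarray:
    """Row-wise 1-df LR chi-square P-values for logit(y) ~ 1 + g,
    Newton-fitted in parallel across replicate rows."""
    reps, n = y.shape
    b0 = np.zeros(reps)
    b1 = np.zeros(reps)
    for _ in range(n_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * g, -30, 30)
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        r0 = (y - mu).sum(axis=1)
        r1 = (g * (y - mu)).sum(axis=1)
        s0 = w.sum(axis=1)
        s1 = (w * g).sum(axis=1)
        s2 = (w * g * g).sum(axis=1)
        det = np.maximum(s0 * s2 - s1 * s1, 1e-30)
        b0 = b0 + (s2 * r0 - s1 * r1) / det
        b1 = b1 + (s0 * r1 - s1 * r0) / det
    eta = np.clip(b0[:, None] + b1[:, None] * g, -30, 30)
    ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
    k = y.sum(axis=1)
    p1 = k / n
    p1 = np.clip(p1, 1e-12, 1 - 1e-12)
    ll0 = k * np.log(p1) + (n - k) * np.log(1 - p1)
    lr = np.maximum(0.0, 2.0 * (ll - ll0))
    return special.chdtrc(1, lr)


def estimate_p_correlation(cell: CalibrationCell, seed=None,
                           chunk: int = 500) -> float:
    """Pearson correlation of the two cross P-values over the cell's
    replicates (simulated under the null)."""
    rng = np.random.default_rng(seed)
    pa_parts, pb_parts = [], []
    left = cell.n_reps
    while left > 0:
        reps = min(chunk, left)
        left -= reps
        g1, g2 = _sample_genotypes(cell, rng, reps)
        z = rng.standard_normal((2, reps, cell.n_subjects))
        if cell.phenotype_type == "quantitative":
            y1 = z[0]
            y2 = cell.rho * z[0] + np.sqrt(1 - cell.rho ** 2) * z[1]
            pa_parts.append(_wald_p_rows(y1, g2))
            pb_parts.append(_wald_p_rows(y2, g1))
        else:
            # bivariate Bernoulli (prevalence 0.5) via a Gaussian copula
            # calibrated so the binary correlation equals rho
            rho_z = np.sin(cell.rho * np.pi / 2.0)  # tetrachoric inverse
            y1 = (z[0] > 0).astype(float)
            zz = rho_z * z[0] + np.sqrt(1 - rho_z ** 2) * z[1]
            y2 = (zz > 0).astype(float)
            pa_parts.append(_logistic_lr_rows(y1, g2))
            pb_parts.append(_logistic_lr_rows(y2, g1))
    pa = np.concatenate(pa_parts)
    pb = np.concatenate(pb_parts)
    return float(np.corrcoef(pa, pb)[0, 1])


def run_grid(rhos=None, rs=None, maf: float = 0.3,
             phenotype_type: str = "quantitative", n_subjects: int = 4000,
             n_reps: int = 2000, seed=None) -> pd.DataFrame:
    """Estimate the P-value correlation over a (rho, r) grid.

    The default grid steps rho and r from 0 to 1 in steps of 0.1 (the
    full range of nonnegative correlations, endpoints included).
    """
    if rhos is None:
        rhos = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    if rs is None:
        rs = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    ss = np.random.SeedSequence(seed)
    rows = []
    for rho in rhos:
        for r in rs:
            cell = CalibrationCell(rho=float(rho), r=float(r), maf1=maf,
                                   phenotype_type=phenotype_type,
                                   n_subjects=n_subjects, n_reps=n_reps)
            est = estimate_p_correlation(cell, seed=ss.spawn(1)[0])
            rows.append({"rho": cell.rho, "r": cell.r, "x": cell.x,
                         "estimate": est,
                         "prediction": pvalue_corr_poly(cell.x)})
    return pd.DataFrame(rows)


def validate_polynomial(grid: pd.DataFrame) -> float:
    """Coefficient of determination of the frozen polynomial against the
    simulated estimates: 1 - SS_res / SS_tot over the grid cells."""
    if len(grid) < 20:
        raise ValueError("need at least 20 grid cells for validation")
    if "x" in grid and pd.Series(grid["x"]).nunique() < 2:
        raise ValueError("degenerate grid: a single X = rho*r value")
    est = grid["estimate"].to_numpy()
    pred = grid["prediction"].to_numpy()
    ss_tot = float(((est - est.mean()) ** 2).sum())
    if ss_tot < 1e-20:
        raise ValueError("degenerate grid: no spread in the estimates")
    ss_res = float(((est - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot
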