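"""Synthetic genotype-phenotype generator and simulation harness.

The generator emulates the simulation study conditions used to assess
multivariate gene-based tests: 2000 unrelated subjects, 20 standard
normal phenotypes, and a gene of 10 SNPs (small) or 60 SNPs (large) with
MAF 0.2 arranged in LD blocks (haplotypic r = 0.9 within a block, 0
between).  Causal SNPs (disease-susceptibility loci, DSL) explain 0.5%
(small gene) or 1% (large gene) of the variance of the variable they are
injected into.

Six trait-generating models relate genotypes to the 20 phenotypes:

* ``factor1-latent``  - one common factor, gene effect on the factor;
* ``factor1-direct``  - one common factor, gene effect on one phenotype;
* ``factor4-latent``  - four correlated factors, gene effect on one factor;
* ``factor4-direct``  - four correlated factors, gene effect on one
  phenotype;
* ``network1``        - mutually related phenotypes whose covariance mimics
  the 1-factor model, gene effect on one phenotype propagating through
  the network;
* ``network4``        - network with four clusters mimicking the 4-factor
  model, likewise.

Within a factor or cluster, phenotypes correlate 0.56; between, 0.13.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assoc import (gates_sum, gates_manova, manova_gene,
                    multiple_regression_gene, wald_linear_matrix)
from .corr_model import (PhenotypeCorrelation, SnpCorrelation,
                         build_test_correlation)
from .simes_core import TestPValueSet, mgas, simes_rejects

__all__ = [
    "GeneModel",
    "TraitModel",
    "Scenario",
    "SCENARIOS",
    "simulate_genotypes",
    "simulate_phenotypes",
    "run_scenario",
]

M_PHENOTYPES = 20
WITHIN_CORR = 0.56
BETWEEN_CORR = 0.13


# ---------------------------------------------------------------------------
# model descriptions


@dataclass(frozen=True)
class GeneModel:
    """LD and causal structure of one simulated gene."""

    n_snps: int
    blocks: tuple  # tuple of tuples of SNP indices, partitioning the SNPs
    maf: float = 0.2
    r_within: float = 0.9
    dsl: tuple = ()
    dsl_signs: tuple = ()
    variance_explained: float = 0.005

    def __post_init__(self):
        flat = sorted(i for b in self.blocks for i in b)
        if flat != list(range(self.n_snps)):
            raise ValueError("blocks must partition the SNP indices")
        if any(i < 0 or i >= self.n_snps for i in self.dsl):
            raise ValueError("DSL indices out of range")
        if self.dsl_signs and len(self.dsl_signs) != len(self.dsl):
            raise ValueError("one sign per DSL required")
        if not 0.0 < self.maf < 1.0:
            raise ValueError("MAF must lie in (0, 1)")
        if not 0.0 <= self.r_within <= 1.0:
            raise ValueError("within-block r must lie in [0, 1] for the "
                             "exchangeable haplotype construction")

    @property
    def signs(self) -> np.ndarray:
        if self.dsl_signs:
            return np.asarray(self.dsl_signs, dtype=float)
        return np.ones(len(self.dsl))

    def snp_corr(self) -> np.ndarray:
        """Model (not empirical) genotype correlation matrix."""
        r = np.zeros((self.n_snps, self.n_snps))
        for b in self.blocks:
            idx = np.asarray(b)
            r[np.ix_(idx, idx)] = self.r_within
        np.fill_diagonal(r, 1.0)
        return r


def _blocks(sizes) -> tuple:
    out, start = [], 0
    for s in sizes:
        out.append(tuple(range(start, start + s)))
        start += s
    return tuple(out)


def small_gene(n_blocks: int = 1, dsl=(), dsl_signs=(),
               variance_explained: float = 0.005) -> GeneModel:
    """Small gene: 10 SNPs in 1 block (or 2 blocks of 5)."""
    sizes = {1: (10,), 2: (5, 5)}[n_blocks]
    return GeneModel(10, _blocks(sizes), dsl=tuple(dsl),
                     dsl_signs=tuple(dsl_signs),
                     variance_explained=variance_explained)


def large_gene(dsl=(), dsl_signs=(),
               variance_explained: float = 0.01) -> GeneModel:
    """Large gene: 60 SNPs in 8 LD blocks (sizes 8,8,8,8,7,7,7,7 -- the
    reference block layout is not published in detail, so an even split
    is used)."""
    return GeneModel(60, _blocks((8, 8, 8, 8, 7, 7, 7, 7)), dsl=tuple(dsl),
                     dsl_signs=tuple(dsl_signs),
                     variance_explained=variance_explained)


@dataclass(frozen=True)
class TraitModel:
    """One of the six trait-generating genotype-phenotype models."""

    kind: str
    m: int = M_PHENOTYPES
    within: float = WITHIN_CORR
    between: float = BETWEEN_CORR
    #: phenotype receiving the direct effect (direct/network kinds) or the
    #: factor receiving the latent effect (latent kinds)
    target: int = 0
    #: single-DSL opposite-effect variant: the DSL affects two phenotypes
    #: (or half a factor's indicators) in opposite directions
    opposite_single: bool = False
    #: for clustered models with ``opposite_single``: second affected
    #: phenotype in the same ("within") or a different ("between") cluster
    opposite_scope: str = "within"

    KINDS = ("factor1-latent", "factor1-direct", "factor4-latent",
             "factor4-direct", "network1", "network4")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown trait model kind {self.kind!r}")
        if self.opposite_scope not in ("within", "between"):
            raise ValueError("opposite_scope must be 'within' or 'between'")

    @property
    def n_clusters(self) -> int:
        return 4 if "4" in self.kind else 1

    @property
    def cluster_size(self) -> int:
        return self.m // self.n_clusters

    def cluster_of(self, pheno: int) -> int:
        return pheno // self.cluster_size

    def implied_corr(self) -> np.ndarray:
        """Target phenotype correlation matrix (no genetic effects)."""
        c = np.full((self.m, self.m), self.between)
        for k in range(self.n_clusters):
            s = slice(k * self.cluster_size, (k + 1) * self.cluster_size)
            c[s, s] = self.within
        np.fill_diagonal(c, 1.0)
        return c


@dataclass(frozen=True)
class Scenario:
    """One simulation cell: a gene model plus a trait model."""

    scenario_id: int
    gene: GeneModel
    trait: TraitModel
    n_blocks: int = 1
    n_dsl: int = 0
    opposite: bool = False

    def with_trait(self, kind: str, **kwargs) -> "Scenario":
        trait = TraitModel(kind=kind,
                           opposite_single=self.opposite and self.n_dsl == 1,
                           **kwargs)
        return replace(self, trait=trait)


def _scenario(sid, size, n_blocks, n_dsl, opposite) -> Scenario:
    if size == "small":
        per_block = {1: 10, 2: 5}[n_blocks]
        if n_blocks == 1:
            dsl = tuple(range(n_dsl))
        else:  # spread DSL one per block
            dsl = tuple(b * per_block for b in range(n_dsl))
        signs = ()
        if opposite and n_dsl > 1:
            signs = tuple(1.0 if i < n_dsl / 2 else -1.0
                          for i in range(n_dsl))
        gene = small_gene(n_blocks, dsl=dsl, dsl_signs=signs,
                          variance_explained=0.005)
    else:
        starts = (0, 8, 16, 24, 32, 39, 46, 53)
        dsl = starts[:n_dsl]
        signs = ()
        if opposite and n_dsl > 1:
            signs = tuple(1.0 if i < n_dsl / 2 else -1.0
                          for i in range(n_dsl))
        gene = large_gene(dsl=dsl, dsl_signs=signs, variance_explained=0.01)
    trait = TraitModel(kind="factor1-latent",
                       opposite_single=opposite and n_dsl == 1)
    return Scenario(sid, gene, trait, n_blocks=n_blocks, n_dsl=n_dsl,
                    opposite=opposite)


#: The 14 simulation scenarios (gene side); combine with any trait model
#: via :meth:`Scenario.with_trait`.
SCENARIOS = {
    1: _scenario(1, "small", 1, 0, False),
    2: _scenario(2, "small", 1, 1, False),
    3: _scenario(3, "small", 1, 1, True),
    4: _scenario(4, "small", 1, 2, False),
    5: _scenario(5, "small", 1, 2, True),
    6: _scenario(6, "small", 1, 4, False),
    7: _scenario(7, "small", 1, 4, True),
    8: _scenario(8, "small", 2, 1, False),
    9: _scenario(9, "small", 2, 2, False),
    10: _scenario(10, "small", 2, 2, True),
    11: _scenario(11, "large", 8, 0, False),
    12: _scenario(12, "large", 8, 1, False),
    13: _scenario(13, "large", 8, 8, False),
    14: _scenario(14, "large", 8, 8, True),
}


# ---------------------------------------------------------------------------
# genotypes


def _haplotypes(n: int, gene: GeneModel, rng: np.random.Generator
                ) -> np.ndarray:
    """One haplotype per subject: exchangeable equicorrelated Bernoulli
    alleles within each block.

    Within a block, allele j is taken from a shared draw with probability
    sqrt(r) and from a private draw otherwise; both draws are Bernoulli
    with the block MAF.  This reproduces the pairwise two-SNP haplotype
    frequencies implied by (maf, r) exactly, for every pair in the block,
    and makes all SNPs of a block exchangeable.
    """
    hap = np.empty((n, gene.n_snps), dtype=np.int8)
    a = np.sqrt(gene.r_within)
    for block in gene.blocks:
        k = len(block)
        shared = rng.random((n, 1)) < gene.maf
        private = rng.random((n, k)) < gene.maf
        use_shared = rng.random((n, k)) < a
        hap[:, block] = np.where(use_shared, shared, private)
    return hap


def simulate_genotypes(n_subjects: int, gene: GeneModel,
                       rng=None) -> np.ndarray:
    """Additive dosage matrix (N x n, values 0/1/2) for one gene.

    Dosages are sums of two independent haplotypes, so the per-SNP allele
    frequency equals ``gene.maf`` and the pairwise genotypic correlation
    equals the haplotypic correlation of the block structure.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(rng)
    g = _haplotypes(n_subjects, gene, rng).astype(np.int8)
    g += _haplotypes(n_subjects, gene, rng)
    return g.astype(float)


def _standardise_dosage(G: np.ndarray, gene: GeneModel) -> np.ndarray:
    """Standardise by the model moments (mean 2*maf, var 2*maf*(1-maf))."""
    return (G - 2.0 * gene.maf) / np.sqrt(2.0 * gene.maf * (1.0 - gene.maf))


def _genetic_component(G: np.ndarray, gene: GeneModel):
    """Weighted DSL sum and its model variance.

    Each DSL enters with weight ``sign * sqrt(v)`` on the standardised
    dosage, so a lone DSL explains exactly ``v`` of the variance of the
    variable it is injected into.  Correlated DSL inflate the joint
    variance through the LD cross terms (and the marginal effect of each
    DSL then exceeds ``v`` -- the LD augmentation effect).
    """
    idx = np.asarray(gene.dsl, dtype=int)
    signs = gene.signs
    v = gene.variance_explained
    gs = _standardise_dosage(G[:, idx], gene)
    comp = gs @ (signs * np.sqrt(v))
    r_sub = gene.snp_corr()[np.ix_(idx, idx)]
    var = float(v * signs @ r_sub @ signs)
    return comp, var


# ---------------------------------------------------------------------------
# network weight solutions


def _network_params(trait: TraitModel):
    """Edge weight(s) and innovation variance for y = W y + e.

    The stationary covariance (I-W)^-1 d I (I-W)^-T shares eigenvectors
    with the block-pattern target correlation, so matching eigenvalues
    gives a closed-form solution: for target eigenvalue mu_i and weight
    eigenvalue nu_i, 1 - nu_i = sqrt(d / mu_i).
    """
    a, b = trait.within, trait.between
    m, c = trait.m, trait.cluster_size
    if trait.n_clusters == 1:
        mu_ones = 1 + (m - 1) * a
        mu_rest = 1 - a
        # nu_ones = (m-1) w, nu_rest = -w
        sd = m / ((m - 1) / np.sqrt(mu_rest) + 1 / np.sqrt(mu_ones))
        d = sd ** 2
        w = sd / np.sqrt(mu_rest) - 1.0
        W = np.full((m, m), w)
        np.fill_diagonal(W, 0.0)
        return W, d
    mu1 = 1 + (c - 1) * a + (m - c) * b      # global ones
    mu2 = 1 + (c - 1) * a - c * b            # cluster contrasts
    mu3 = 1 - a                              # within-cluster contrasts
    # nu1 = (c-1) w1 + (m-c) w2, nu2 = (c-1) w1 - c w2, nu3 = -w1
    k = trait.n_clusters
    coef = k * (c - 1) / np.sqrt(mu3) + (k - 1) / np.sqrt(mu2) \
        + 1 / np.sqrt(mu1)
    sd = m / coef
    d = sd ** 2
    w1 = sd / np.sqrt(mu3) - 1.0
    w2 = ((c - 1) * w1 - (1.0 - sd / np.sqrt(mu2))) / c
    W = np.full((m, m), w2)
    for j in range(k):
        s = slice(j * c, (j + 1) * c)
        W[s, s] = w1
    np.fill_diagonal(W, 0.0)
    return W, d


# ---------------------------------------------------------------------------
# phenotypes


def _affected_pair(trait: TraitModel):
    """The two phenotypes hit by a single opposite-effect DSL.

    By convention the first phenotype of the target cluster and either
    its neighbour (same cluster) or the first phenotype of the next
    cluster (different clusters)."""
    c = trait.cluster_size
    base = trait.target * c if "4" in trait.kind else 0
    if trait.opposite_scope == "within" or trait.n_clusters == 1:
        return base, base + 1
    return base, (base + c) % trait.m


def simulate_phenotypes(G: np.ndarray, trait: TraitModel, gene: GeneModel,
                        rng=None) -> np.ndarray:
    """N x m phenotype matrix with standard-normal margins.

    Genetic effects are injected at the latent factor, at one phenotype,
    or into one phenotype's network innovation, per ``trait.kind``; the
    directly affected variable's remaining variance is rescaled so its
    model variance stays 1.  Variance explained is defined at the point
    of injection, before propagation through loadings or the network.
    """
    rng = np.random.default_rng(rng)
    n = G.shape[0]
    m = trait.m
    has_dsl = len(gene.dsl) > 0
    comp, var = _genetic_component(G, gene) if has_dsl else (None, 0.0)
    if var >= 1.0:
        raise ValueError("combined DSL effects exceed unit variance")

    lam = np.sqrt(trait.within)
    resid_sd = np.sqrt(1.0 - trait.within)

    if trait.kind.startswith("factor"):
        k = trait.n_clusters
        if k == 1:
            factors = rng.standard_normal((n, 1))
        else:
            rho_f = trait.between / trait.within
            cf = np.full((k, k), rho_f)
            np.fill_diagonal(cf, 1.0)
            factors = rng.standard_normal((n, k)) @ np.linalg.cholesky(cf).T
        assign = np.repeat(np.arange(k), trait.cluster_size)
        y = lam * factors[:, assign] + resid_sd * rng.standard_normal((n, m))
        if not has_dsl:
            return y
        if trait.kind.endswith("latent") and not trait.opposite_single:
            f = comp + np.sqrt(1.0 - var) * factors[:, trait.target]
            cols = assign == trait.target
            y[:, cols] = lam * f[:, None] \
                + resid_sd * rng.standard_normal((n, int(cols.sum())))
            return y
        if trait.kind.endswith("latent") and trait.opposite_single:
            # the lone DSL hits half the factor's indicators +, half -
            members = np.flatnonzero(assign == trait.target)
            half = (len(members) + 1) // 2
            for i, ph in enumerate(members):
                s = 1.0 if i < half else -1.0
                y[:, ph] = s * comp + np.sqrt(1.0 - var) * y[:, ph]
            return y
        # direct kinds
        if trait.opposite_single:
            p1, p2 = _affected_pair(trait)
            y[:, p1] = comp + np.sqrt(1.0 - var) * y[:, p1]
            y[:, p2] = -comp + np.sqrt(1.0 - var) * y[:, p2]
        else:
            t = trait.target if trait.kind == "factor1-direct" \
                else trait.target * trait.cluster_size
            y[:, t] = comp + np.sqrt(1.0 - var) * y[:, t]
        return y

    # network kinds
    W, d = _network_params(trait)
    eps = np.sqrt(d) * rng.standard_normal((n, m))
    if has_dsl:
        sd_d = np.sqrt(d)
        if trait.opposite_single:
            p1, p2 = _affected_pair(trait)
            eps[:, p1] = sd_d * (comp + np.sqrt(1.0 - var)
                                 * rng.standard_normal(n))
            eps[:, p2] = sd_d * (-comp + np.sqrt(1.0 - var)
                                 * rng.standard_normal(n))
        else:
            t = trait.target * trait.cluster_size if "4" in trait.kind \
                else trait.target
            eps[:, t] = sd_d * (comp + np.sqrt(1.0 - var)
                                * rng.standard_normal(n))
    solve = np.linalg.inv(np.eye(m) - W)
    return eps @ solve.T


# ---------------------------------------------------------------------------
# experiment harness

ALL_METHODS = ("gates_sum", "multiple_regression", "manova",
               "gates_manova", "mgas")


def _empirical_corr(X: np.ndarray) -> np.ndarray:
    c = np.corrcoef(X, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def _method_pvalue(method, Y, G, sigma, omega, alpha, need_p):
    """Return (p_value or None, rejected) for one replicate and method."""
    if method == "mgas":
        P = wald_linear_matrix(Y, G)
        tests = TestPValueSet(np.clip(P, 1e-300, 1.0),
                              sigma.labels, omega.labels)
        if need_p:
            res = mgas(tests, sigma, omega, divide_conquer=False)
            return res.p_value, res.p_value <= alpha
        phi = build_test_correlation(sigma, omega).values
        flat = tests.pvalues.ravel()
        order = np.argsort(flat, kind="stable")
        rej = simes_rejects(flat[order], phi[np.ix_(order, order)], alpha)
        return None, rej
    if method == "gates_sum":
        p = gates_sum(Y, G, omega).p_value
    elif method == "multiple_regression":
        p = multiple_regression_gene(Y, G)
    elif method == "manova":
        p = manova_gene(Y, G)
    elif method == "gates_manova":
        p = gates_manova(Y, G, omega).p_value
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, p <= alpha


def run_scenario(scenario: Scenario, n_reps: int, n_subjects: int = 2000,
                 alpha: float = 0.05, methods=ALL_METHODS, seed=None,
                 collect_pvalues: bool = False) -> pd.DataFrame:
    """Rejection rates of the gene-based tests over simulated replicates.

    Per replicate a fresh genotype/phenotype sample is drawn, the
    phenotype and SNP correlation matrices are estimated empirically
    from that replicate (matching analysis practice), and each method's
    gene-level P-value is compared with ``alpha``.

    Returns a table with one row per method: rejection count, rate and
    binomial standard error (plus the P-values when
    ``collect_pvalues``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    gene, trait = scenario.gene, scenario.trait
    counts = {meth: 0 for meth in methods}
    pvals = {meth: [] for meth in methods} if collect_pvalues else None
    for _ in range(n_reps):
        G = simulate_genotypes(n_subjects, gene, rng)
        Y = simulate_phenotypes(G, trait, gene, rng)
        sigma = PhenotypeCorrelation(
            tuple(f"pheno{i}" for i in range(trait.m)), _empirical_corr(Y))
        omega = SnpCorrelation(
            tuple(f"snp{i}" for i in range(gene.n_snps)), _empirical_corr(G))
        for meth in methods:
            p, rej = _method_pvalue(meth, Y, G, sigma, omega, alpha,
                                    collect_pvalues)
            counts[meth] += bool(rej)
            if collect_pvalues:
                pvals[meth].append(p)
    rows = []
    for meth in methods:
        rate = counts[meth] / n_reps
        se = np.sqrt(rate * (1.0 - rate) / n_reps)
        rows.append({"method": meth, "n_reps": n_reps,
                     "rejections": counts[meth], "rate": rate, "se": se})
    out = pd.DataFrame(rows)
    if collect_pvalues:
        out.attrs["pvalues"] = {k: np.asarray(v) for k, v in pvals.items()}
    return out
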