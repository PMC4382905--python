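"""Effective number of independent P-values by eigendecomposition.

Among j correlated tests, the effective number of independent P-values is

    q_ej = j - sum_i I(lambda_i) (lambda_i - 1)

where lambda_i are the eigenvalues of the j x j correlation submatrix of
the top-j ordered tests and the indicator I keeps only eigenvalues above
1.  Independent tests give q_ej = j, perfectly correlated tests give
q_ej = 1.  The gene-level statistic weights the j-th ordered P-value by
q_e / q_ej, with q_e the effective number over all tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corr_model import TestCorrelation

__all__ = ["EffectiveNumberResult", "effective_number", "weight_sequence"]

#: Eigenvalues within this distance of 1 are treated as <= 1, avoiding
#: floating-point flicker of the indicator at the boundary.
EIG_TOL = 1e-10


def _as_matrix(phi) -> np.ndarray:
    if isinstance(phi, TestCorrelation):
        return phi.values
    return np.asarray(phi, dtype=float)


def effective_number(phi_sub, j: int | None = None) -> float:
    """Effective number of independent P-values among j correlated tests.

    Parameters
    ----------
    phi_sub : array-like or TestCorrelation
        The j x j correlation submatrix of the top-j ordered tests.
    j : int, optional
        Expected dimension; validated against ``phi_sub`` when given.

    Returns
    -------
    float
        ``j - sum(lambda_i - 1 for lambda_i > 1)``, floored at 1.  The
        floor matters only when the polynomial-mapped matrix is slightly
        non-PSD: by definition the effective number of at least one test
        is at least 1.
    """
    mat = _as_matrix(phi_sub)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("correlation submatrix must be symmetric")
    if j is not None and mat.shape[0] != j:
        raise ValueError(f"matrix dimension {mat.shape[0]} != j = {j}")
    dim = mat.shape[0]
    if dim == 1:
        return 1.0
    lam = np.linalg.eigvalsh(mat)
    excess = lam - 1.0
    qej = dim - excess[excess > EIG_TOL].sum()
    return max(1.0, float(qej))


@dataclass(frozen=True)
class EffectiveNumberResult:
    """Effective numbers q_ej for every prefix j and the derived weights.

    ``weights[j-1] = q_e / q_ej`` multiplies the j-th smallest P-value in
    the extended Simes statistic; the weight of the last-ranked test is
    exactly 1 and all weights are floored at 1 (q_e >= q_ej by
    definition; the floor enforces it under numerical noise).
    """

    q_ej: np.ndarray = field(repr=False)
    q_e: float = 0.0
    weights: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "q_ej", np.asarray(self.q_ej, dtype=float))
        if self.weights is None:
            w = np.maximum(self.q_e / self.q_ej, 1.0)
            object.__setattr__(self, "weights", w)


def weight_sequence(phi, order=None, max_rank: int | None = None
                    ) -> EffectiveNumberResult:
    """Compute q_ej for each prefix of the ordered tests and the weights.

    Parameters
    ----------
    phi : TestCorrelation or array-like
        Correlation matrix of all tests (any consistent ordering).
    order : sequence of int, optional
        Permutation placing the tests in ascending P-value order.
        Defaults to the identity (useful for the deterministic worked
        examples, where the matrix ordering is already the one wanted).
    max_rank : int, optional
        Compute q_ej only for prefixes j <= max_rank (q_e is always
        computed from the full matrix).  Each prefix costs a full
        eigendecomposition, so restricting the rank keeps large matrices
        affordable when only the leading weights are needed.

    Returns
    -------
    EffectiveNumberResult
    """
    mat = _as_matrix(phi)
    t = mat.shape[0]
    if order is None:
        ordered = mat
    else:
        order = np.asarray(order)
        if sorted(order.tolist()) != list(range(t)):
            raise ValueError("order must be a permutation of 0..T-1")
        ordered = mat[np.ix_(order, order)]
    q_e = effective_number(ordered)
    upto = t if max_rank is None else min(int(max_rank), t)
    q_ej = np.empty(upto)
    for j in range(1, upto + 1):
        q_ej[j - 1] = effective_number(ordered[:j, :j])
    return EffectiveNumberResult(q_ej=q_ej, q_e=q_e)
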