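"""Total-effect regression and the SVD expansion of the effect matrix.

The model behind the package: observed methylation Y (m CpGs x n samples)
mixes cell-type-specific profiles M with sample proportions Omega, plus a
direct (non-cell-mediated) phenotype effect B and noise,

    Y = B X^T + M Omega^T + E.

A row-wise ordinary least squares fit of Y on the design X gives the total
effect A (m x d) and residuals R (m x n).  Because the cell-profile space
dominates the variation in both A and R, a thin SVD of the concatenation
[A R] = U diag(lambda) V^T separates the effect into rank-one terms
Q_j = u_j v*_j^T (v*_j = first d coordinates of v_j) whose leading k terms

    Delta_k = sum_{j<=k} lambda_j Q_j

estimate the cell-composition-mediated effect, with B_k = A - Delta_k the
remainder attributed to direct effects.  Delta_k and B_k are orthogonal by
construction (U has orthonormal columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import BetaMatrix, DesignMatrix

__all__ = [
    "TotalEffectFit",
    "EffectDecomposition",
    "EffectPartition",
    "fit_total_effect",
    "svd_expansion",
    "partition_effect",
    "expansion_term",
]

#: Relative cutoff below which trailing singular values are treated as zero.
RANK_TOL = 1e-12


@dataclass
class TotalEffectFit:
    """Row-wise OLS fit: A (m x d) total effects and R (m x n) residuals."""

    A: np.ndarray
    R: np.ndarray
    design: DesignMatrix
    cpg_ids: list
    covariate_names: list


@dataclass
class EffectDecomposition:
    """Thin SVD factors of [A R] restricted to what the partition needs.

    ``Vstar`` holds the first d coordinates of each retained right singular
    vector, one column per term, so that A = U diag(lambdas) Vstar^T.
    """

    U: np.ndarray
    lambdas: np.ndarray
    Vstar: np.ndarray
    A: np.ndarray
    cpg_ids: list
    covariate_names: list

    @property
    def rank(self) -> int:
        return int(self.lambdas.size)

    @property
    def m(self) -> int:
        return self.U.shape[0]

    @property
    def d(self) -> int:
        return self.Vstar.shape[0]


@dataclass
class EffectPartition:
    """Split of the total effect at dimension k: A = Delta + B."""

    k: int
    Delta: np.ndarray
    B: np.ndarray


def _impute_row_means(values: np.ndarray) -> np.ndarray:
    """Replace NaNs by their row mean; rows must not be all-missing."""
    out = np.array(values, dtype=float, copy=True)
    missing = ~np.isfinite(out)
    if not missing.any():
        return out
    bad_rows = missing.all(axis=1)
    if bad_rows.any():
        raise ValueError(
            f"{int(bad_rows.sum())} rows are entirely missing; "
            "filter them out when reading the beta matrix"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(out, axis=1)
    rows, cols = np.where(missing)
    out[rows, cols] = row_means[rows]
    return out


def fit_total_effect(
    Y: BetaMatrix, X: DesignMatrix, impute: str = "row-mean"
) -> TotalEffectFit:
    """Fit per-CpG ordinary least squares of beta values on the design.

    Parameters
    ----------
    Y
        Beta matrix (m x n).  Missing entries are mean-imputed per row
        when ``impute='row-mean'``; with ``impute='none'`` any missing
        value raises.
    X
        Design matrix (n x d), intercept first, full column rank.

    Returns
    -------
    TotalEffectFit
        A (m x d) least-squares coefficients and R = Y - A X^T.
    """
    if Y.n != X.n:
        raise ValueError(f"sample mismatch: beta has {Y.n} columns, design {X.n} rows")
    if X.n < X.d + 2:
        raise ValueError(
            f"need n >= d + 2 samples for residual degrees of freedom "
            f"(n={X.n}, d={X.d})"
        )
    if impute == "row-mean":
        values = _impute_row_means(Y.values)
    elif impute == "none":
        if not np.isfinite(Y.values).all():
            raise ValueError("missing beta values present and impute='none'")
        values = Y.values
    else:
        raise ValueError(f"unknown missing-value policy: {impute!r}")

    # A^T solves the normal equations for every CpG row at once.
    At, *_ = np.linalg.lstsq(X.values, values.T, rcond=None)
    A = At.T
    R = values - A @ X.values.T
    return TotalEffectFit(
        A=A, R=R, design=X, cpg_ids=list(Y.cpg_ids), covariate_names=list(X.column_names)
    )


def svd_expansion(fit: TotalEffectFit, rel_tol: float = RANK_TOL) -> EffectDecomposition:
    """Thin SVD of the concatenation [A R], keeping non-negligible terms.

    Terms with singular value <= ``rel_tol`` times the largest are dropped:
    the concatenation has at most min(m, n + d) non-zero singular values
    and in practice rank <= n, so trailing terms are numerically zero.
    """
    concat = np.hstack([fit.A, fit.R])
    scale = np.linalg.norm(concat)
    if scale == 0.0:
        raise ValueError("degenerate input: [A R] is identically zero")
    U, lam, Vt = np.linalg.svd(concat, full_matrices=False)
    keep = lam > rel_tol * lam[0]
    d = fit.A.shape[1]
    return EffectDecomposition(
        U=U[:, keep],
        lambdas=lam[keep],
        Vstar=Vt[keep, :d].T,
        A=fit.A,
        cpg_ids=fit.cpg_ids,
        covariate_names=fit.covariate_names,
    )


#: Ratio lambda_k / lambda_{k+1} under which the split is flagged ill-conditioned.
BOUNDARY_RATIO = 1.01


def partition_effect(dec: EffectDecomposition, k: int) -> EffectPartition:
    """Split A into Delta_k (first k SVD terms) and B_k = A - Delta_k."""
    if not 0 <= k <= dec.rank:
        raise ValueError(f"k={k} outside valid range [0, {dec.rank}]")
    if 0 < k < dec.rank and dec.lambdas[k] > 0:
        if dec.lambdas[k - 1] / dec.lambdas[k] < BOUNDARY_RATIO:
            warnings.warn(
                f"singular values {k} and {k + 1} nearly degenerate "
                f"(ratio {dec.lambdas[k - 1] / dec.lambdas[k]:.4f}); "
                "the Delta/B split at this k is ill-conditioned",
                RuntimeWarning,
                stacklevel=2,
            )
    if k == 0:
        Delta = np.zeros_like(dec.A)
    else:
        Delta = (dec.U[:, :k] * dec.lambdas[:k]) @ dec.Vstar[:, :k].T
    return EffectPartition(k=k, Delta=Delta, B=dec.A - Delta)


def expansion_term(dec: EffectDecomposition, j: int) -> np.ndarray:
    """The j-th additive term lambda_j u_j v*_j^T (1-based j)."""
    if not 1 <= j <= dec.rank:
        raise ValueError(f"term index j={j} outside valid range [1, {dec.rank}]")
    i = j - 1
    return dec.lambdas[i] * np.outer(dec.U[:, i], dec.Vstar[:, i])
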