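"""Selection of the dimension parameter k.

k counts the leading SVD terms attributed to cell composition.  Three
selectors are provided:

* ``rmsd`` — for each candidate k, the median (across CpGs) of the
  root-mean-square change in Delta_k over the non-intercept covariate
  columns when moving from k-1 to k; the k minimising this median marks
  the start of the "stable" region where adding terms barely moves the
  cell-composition estimate.
* ``boot-t`` — same idea applied to bootstrap t-statistics of Delta_k
  rather than raw coefficients, minimising the median row-sum of squared
  successive differences.
* ``rmt`` — a random-matrix-theory bound: the number of eigenvalues of the
  residual covariance exceeding the Marchenko-Pastur upper edge, i.e. the
  number of residual components inconsistent with pure noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .containers import BetaMatrix, DesignMatrix
from .decomposition import (
    EffectDecomposition,
    _impute_row_means,
    fit_total_effect,
    partition_effect,
    svd_expansion,
)

__all__ = [
    "RmsdProfile",
    "rmsd_profile",
    "select_k_rmsd",
    "select_k_bootstrap_t",
    "select_k_rmt",
    "default_k_range",
]


@dataclass
class RmsdProfile:
    """Per-k stability statistic (beta units) and its minimiser."""

    k_values: np.ndarray
    rmsd: np.ndarray

    def __post_init__(self):
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if self.k_values.size != self.rmsd.size or self.k_values.size == 0:
            raise ValueError("k_values and rmsd must be non-empty and equal length")
        if (self.rmsd < 0).any():
            raise ValueError("rmsd statistics must be non-negative")

    @property
    def selected_k(self) -> int:
        return select_k_rmsd(self)


def default_k_range(n: int, d: int, small_array: bool = True) -> range:
    """Candidate k values: 1..25 for small arrays, 1..50 otherwise, capped
    by the residual degrees of freedom."""
    cap = 25 if small_array else 50
    upper = min(cap, n - d - 1)
    if upper < 1:
        raise ValueError("too few residual degrees of freedom for any candidate k")
    return range(1, upper + 1)


def rmsd_profile(
    dec: EffectDecomposition,
    k_range=None,
    use_next_term: bool = False,
) -> RmsdProfile:
    """Median root-mean-square difference between successive Delta_k.

    For each candidate k the statistic is

        RMSD_k = median_h sqrt( (d-1)^{-1} sum_{l=2..d}
                                (lambda_k U[h,k] Vstar[l,k])^2 ),

    the per-CpG RMS of Delta_k - Delta_{k-1} = lambda_k Q_k over the
    non-intercept columns, with the median over CpG rows h.  With
    ``use_next_term`` the increment lambda_{k+1} Q_{k+1} is used instead
    (the same profile shifted by one position).
    """
    d = dec.d
    if d < 2:
        raise ValueError(
            "RMSD criterion needs at least one non-intercept design column"
        )
    if k_range is None:
        k_range = range(1, dec.rank + 1)
    k_values = np.asarray(sorted(k_range), dtype=int)
    if k_values.size == 0 or k_values[0] < 1 or k_values[-1] > dec.rank:
        raise ValueError(f"k_range must lie within [1, {dec.rank}]")
    stats = np.empty(k_values.size)
    for i, k in enumerate(k_values):
        j = k + 1 if use_next_term else k
        if j > dec.rank:
            stats[i] = 0.0
            continue
        # row-wise RMS of lambda_j * U[:, j] * Vstar[l, j] over l = 2..d
        v_tail = dec.Vstar[1:, j - 1]
        row_rms = (
            np.abs(dec.lambdas[j - 1] * dec.U[:, j - 1])
            * np.sqrt(np.sum(v_tail**2) / (d - 1))
        )
        stats[i] = float(np.median(row_rms))
    return RmsdProfile(k_values=k_values, rmsd=stats)


def select_k_rmsd(profile: RmsdProfile) -> int:
    """Argmin of the RMSD profile; ties resolve to the smallest k."""
    return int(profile.k_values[int(np.argmin(profile.rmsd))])


def select_k_bootstrap_t(
    Y: BetaMatrix,
    X: DesignMatrix,
    k_range=None,
    n_boot: int = 50,
    seed: int = 0,
) -> int:
    """Dimension selection on bootstrap t-statistics of Delta_k.

    One set of subject-resampling bootstrap replicates is shared across
    all candidate k (a paired comparison, which removes replicate-to-
    replicate Monte-Carlo noise from the between-k contrast).  For each k
    the element-wise t = Delta_k / SE_boot(Delta_k) is formed and the
    criterion is the median across CpGs of the row-sum over non-intercept
    columns of (t_k - t_{k-1})^2; the minimising k is returned, ties to
    the smallest.  Entries with zero bootstrap SE are excluded from the
    row sums with a warning.
    """
    if n_boot < 25:
        raise ValueError("bootstrap-t selection needs n_boot >= 25")
    if X.d < 2:
        raise ValueError("bootstrap-t criterion needs a non-intercept column")
    fit = fit_total_effect(Y, X)
    dec = svd_expansion(fit)
    if k_range is None:
        k_range = default_k_range(X.n, X.d)
    k_values = sorted(set(int(k) for k in k_range))
    if k_values[0] < 1:
        raise ValueError("candidate k must be at least 1")
    # candidates beyond the retained rank add only zero terms; clamp there
    ks_needed = sorted({k for k in k_values} | {k - 1 for k in k_values if k >= 2})

    rng = np.random.default_rng(seed)
    m, d = fit.A.shape
    n = X.n
    values = _impute_row_means(Y.values)
    sums = {k: np.zeros((m, d)) for k in ks_needed}
    sqsums = {k: np.zeros((m, d)) for k in ks_needed}
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb = X.values[idx]
        if np.linalg.matrix_rank(Xb) < d:
            continue
        Ab, *_ = np.linalg.lstsq(Xb, values[:, idx].T, rcond=None)
        Ab = Ab.T
        Rb = values[:, idx] - Ab @ Xb.T
        Ub, lamb, Vtb = np.linalg.svd(np.hstack([Ab, Rb]), full_matrices=False)
        Vstarb = Vtb[:, :d].T
        for k in ks_needed:
            kk = min(k, lamb.size)
            Dk = (Ub[:, :kk] * lamb[:kk]) @ Vstarb[:, :kk].T
            sums[k] += Dk
            sqsums[k] += Dk**2
        done += 1

    def t_matrix(k: int) -> np.ndarray:
        if k == 0:
            return np.zeros((m, d))
        point = partition_effect(dec, min(k, dec.rank)).Delta
        var = sqsums[k] / n_boot - (sums[k] / n_boot) ** 2
        se = np.sqrt(np.maximum(var, 0.0) * n_boot / (n_boot - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = point / se
        zero = se == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} coefficient entries have zero bootstrap SE; "
                "excluded from the bootstrap-t criterion",
                RuntimeWarning,
                stacklevel=2,
            )
            t[zero] = np.nan
        return t

    crit = np.empty(len(k_values))
    for i, k in enumerate(k_values):
        diff = t_matrix(k)[:, 1:] - t_matrix(k - 1)[:, 1:]
        rowsum = np.nansum(diff**2, axis=1)
        crit[i] = float(np.median(rowsum))
    return int(k_values[int(np.argmin(crit))])


def _mp_median(gamma: float) -> float:
    """Median of the Marchenko-Pastur law with ratio gamma < 1, sigma = 1."""
    a = (1.0 - np.sqrt(gamma)) ** 2
    b = (1.0 + np.sqrt(gamma)) ** 2

    def density(x):
        return np.sqrt((b - x) * (x - a)) / (2.0 * np.pi * gamma * x)

    def cdf_minus_half(x):
        val, _ = integrate.quad(density, a, x, limit=200)
        return val - 0.5

    return float(optimize.brentq(cdf_minus_half, a + 1e-12, b - 1e-12))


#: Upper quantiles of the Tracy-Widom (beta = 1) distribution.
_TW1_QUANTILES = {0.95: 0.9793, 0.99: 2.0234, 0.999: 3.2724}


def select_k_rmt(R: np.ndarray, scale_rows: bool = True, tw_quantile: float = 0.99) -> int:
    """Count residual components exceeding the random-matrix noise edge.

    Rows of the m x n residual matrix are centered (and scaled to unit
    variance when ``scale_rows``); the estimate is the number of
    eigenvalues of R^T R / m above the upper support edge of the
    Marchenko-Pastur law, (1 + sqrt(n/m))^2 * sigma^2.  Because the
    largest noise eigenvalue fluctuates above the asymptotic edge with
    appreciable probability at finite size, the edge carries the
    Johnstone finite-sample allowance: the threshold is the
    ``tw_quantile`` point of the Tracy-Widom null law of the largest
    eigenvalue.  With scaling sigma^2 = 1; without, sigma^2 is estimated
    as the median eigenvalue divided by the median of the unit-variance
    Marchenko-Pastur law (robust to a few signal eigenvalues).
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2:
        raise ValueError("residual matrix must be 2-d")
    m, n = R.shape
    if n >= m:
        raise ValueError(
            f"RMT estimator needs more CpGs than samples (got m={m}, n={n})"
        )
    R = R - R.mean(axis=1, keepdims=True)
    if scale_rows:
        sd = R.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all rows have zero variance after centering")
        R = R[keep] / sd[keep, None]
        m = R.shape[0]
    gamma = n / m
    eigs = np.linalg.eigvalsh(R.T @ R / m)
    if tw_quantile not in _TW1_QUANTILES:
        raise ValueError(f"tw_quantile must be one of {sorted(_TW1_QUANTILES)}")
    # Johnstone largest-eigenvalue null: (l1 - mu)/s ~ TW1, on the
    # eigenvalue scale of R^T R / m
    mu = (np.sqrt(m - 1) + np.sqrt(n)) ** 2 / m
    s_tw = (
        (np.sqrt(m - 1) + np.sqrt(n))
        * (1.0 / np.sqrt(m - 1) + 1.0 / np.sqrt(n)) ** (1.0 / 3.0)
        / m
    )
    threshold = mu + _TW1_QUANTILES[tw_quantile] * s_tw
    if scale_rows:
        sigma2 = 1.0
    else:
        sigma2 = float(np.median(eigs)) / _mp_median(gamma)
    return int(np.sum(eigs > threshold * sigma2))
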