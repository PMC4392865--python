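"""Bootstrap inference for the decomposition coefficients.

Standard errors for A, Delta_k and B_k come from a subject (column)
bootstrap: samples are drawn with replacement and the whole pipeline —
row-wise OLS, SVD of [A R], partition at k — is refit on each replicate.
Resampling subjects rather than CpGs preserves the strong cross-CpG
dependence induced by shared cell composition.  Wald z-statistics against
a standard-normal (or optionally Student-t) reference give p-values, and
false-discovery q-values are computed per coefficient column with either
the Benjamini-Hochberg step-up or Storey's pi0-adaptive variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .containers import BetaMatrix, DesignMatrix
from .decomposition import _impute_row_means, fit_total_effect, svd_expansion

__all__ = [
    "BootstrapDistribution",
    "bootstrap_decomposition",
    "coefficient_tests",
    "qvalues",
    "coefficient_table",
    "decomposition_tables",
]

logger = logging.getLogger(__name__)

#: Replicates whose lambda_k / lambda_{k+1} falls under this ratio are
#: logged as boundary-unstable (the Delta/B split there is ill-conditioned).
_BOUNDARY_RATIO = 1.01


@dataclass
class BootstrapDistribution:
    """Replicate means and standard deviations of Delta_k and B_k."""

    n_boot: int
    k: int
    seed: int
    mean_A: np.ndarray
    se_A: np.ndarray
    mean_Delta: np.ndarray
    se_Delta: np.ndarray
    mean_B: np.ndarray
    se_B: np.ndarray
    n_degenerate_redraws: int = 0
    n_boundary_unstable: int = 0


def bootstrap_decomposition(
    Y: BetaMatrix,
    X: DesignMatrix,
    k: int,
    n_boot: int = 100,
    seed: int = 0,
) -> BootstrapDistribution:
    """Subject-resampling bootstrap of the full decomposition pipeline.

    Each replicate draws n samples with replacement (columns of Y with the
    matching design rows), refits OLS, the SVD expansion and the partition
    at ``k``, and accumulates per-entry means and standard deviations.
    Replicates with a singular resampled design (e.g. a factor level lost)
    are redrawn; more than 100 consecutive redraws raises.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    fit = fit_total_effect(Y, X)
    dec = svd_expansion(fit)
    if not 0 <= k <= dec.rank:
        raise ValueError(f"k={k} outside the rank of the original fit ({dec.rank})")
    values = _impute_row_means(Y.values)
    m, d = fit.A.shape
    n = X.n
    rng = np.random.default_rng(seed)

    acc = {name: [np.zeros((m, d)), np.zeros((m, d))] for name in ("A", "Delta", "B")}
    n_degenerate = 0
    n_boundary = 0
    done = 0
    while done < n_boot:
        consecutive = 0
        while True:
            idx = rng.integers(0, n, size=n)
            Xb = X.values[idx]
            if np.linalg.matrix_rank(Xb) == d:
                break
            consecutive += 1
            n_degenerate += 1
            if consecutive > 100:
                raise RuntimeError(
                    "bootstrap design singular in >100 consecutive redraws; "
                    "the design is too sparse to bootstrap"
                )
        Ab, *_ = np.linalg.lstsq(Xb, values[:, idx].T, rcond=None)
        Ab = Ab.T
        Rb = values[:, idx] - Ab @ Xb.T
        Ub, lamb, Vtb = np.linalg.svd(np.hstack([Ab, Rb]), full_matrices=False)
        kk = min(k, int(np.sum(lamb > 1e-12 * lamb[0])))
        if 0 < kk < lamb.size and lamb[kk] > 0 and lamb[kk - 1] / lamb[kk] < _BOUNDARY_RATIO:
            n_boundary += 1
        Vstarb = Vtb[:, :d].T
        Db = (Ub[:, :kk] * lamb[:kk]) @ Vstarb[:, :kk].T if kk else np.zeros((m, d))
        for name, mat in (("A", Ab), ("Delta", Db), ("B", Ab - Db)):
            acc[name][0] += mat
            acc[name][1] += mat**2
        done += 1

    def finish(name):
        s, s2 = acc[name]
        mean = s / n_boot
        if n_boot == 1:
            return mean, np.zeros((m, d))
        var = (s2 - n_boot * mean**2) / (n_boot - 1)
        return mean, np.sqrt(np.maximum(var, 0.0))

    mean_A, se_A = finish("A")
    mean_D, se_D = finish("Delta")
    mean_B, se_B = finish("B")
    if n_degenerate:
        logger.info("bootstrap: %d degenerate replicates redrawn", n_degenerate)
    if n_boundary:
        logger.info(
            "bootstrap: %d replicates boundary-unstable at k=%d", n_boundary, k
        )
    return BootstrapDistribution(
        n_boot=n_boot,
        k=k,
        seed=seed,
        mean_A=mean_A,
        se_A=se_A,
        mean_Delta=mean_D,
        se_Delta=se_D,
        mean_B=mean_B,
        se_B=se_B,
        n_degenerate_redraws=n_degenerate,
        n_boundary_unstable=n_boundary,
    )


def coefficient_tests(
    point: np.ndarray,
    se: np.ndarray,
    reference: str = "normal",
    df: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Wald z-statistics and two-sided p-values for coefficient estimates.

    ``reference='normal'`` uses p = 2 * Phi(-|z|); ``reference='t'`` uses a
    Student-t tail with ``df`` degrees of freedom.  Degenerate entries with
    zero SE get p = 0 when the estimate is non-zero (certain effect) and
    p = 1 when it is zero.
    """
    point = np.asarray(point, dtype=float)
    se = np.asarray(se, dtype=float)
    if point.shape != se.shape:
        raise ValueError("estimate and SE shapes differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = point / se
    zero = se == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} entries have zero SE; p set to 0/1 by estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    if reference == "normal":
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif reference == "t":
        if df is None or df < 1:
            raise ValueError("t reference requires positive df")
        p = 2.0 * stats.t.sf(np.abs(z), df)
    else:
        raise ValueError(f"unknown reference distribution: {reference!r}")
    p = np.where(zero & (point != 0), 0.0, p)
    p = np.where(zero & (point == 0), 1.0, p)
    with np.errstate(invalid="ignore"):
        z = np.where(zero, np.sign(point) * np.inf, z)
    z = np.where(zero & (point == 0), 0.0, z)
    return z, p


_STOREY_LAMBDA = np.arange(0.05, 0.96, 0.05)


def _storey_pi0(p: np.ndarray) -> float:
    """Storey's pi0: spline-smoothed tail estimates evaluated at lambda=0.95."""
    m = p.size
    pi0_at = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in _STOREY_LAMBDA]
    )
    spline = interpolate.UnivariateSpline(_STOREY_LAMBDA, pi0_at, k=3)
    pi0 = float(spline(_STOREY_LAMBDA[-1]))
    if pi0 <= 0.0:
        pi0 = 1.0 / m  # degenerate extrapolation; keep pi0 strictly positive
    return min(pi0, 1.0)


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """False-discovery q-values from a vector of p-values.

    ``storey`` estimates the null proportion pi0 from the flat right tail
    of the p-value distribution (lambda grid 0.05..0.95, cubic smoothing
    spline evaluated at 0.95, clipped to (0, 1]); ``bh`` is the
    Benjamini-Hochberg step-up, i.e. the same construction with pi0 = 1.
    In both cases q_(i) = min_{j >= i} pi0 * m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "storey" and m < 10:
        warnings.warn(
            "fewer than 10 p-values: falling back to Benjamini-Hochberg",
            RuntimeWarning,
            stacklevel=2,
        )
        method = "bh"
    if method == "storey":
        pi0 = _storey_pi0(p)
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown q-value method: {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def coefficient_table(
    estimates: np.ndarray,
    se: np.ndarray,
    cpg_ids,
    covariate_names,
    q_method: str = "storey",
    reference: str = "normal",
    df: int | None = None,
) -> pd.DataFrame:
    """Long-format table (cpg, covariate, estimate, se, z, p, q).

    q-values are computed separately within each covariate column, never
    pooled across columns.
    """
    z, p = coefficient_tests(estimates, se, reference=reference, df=df)
    frames = []
    for j, name in enumerate(covariate_names):
        frames.append(
            pd.DataFrame(
                {
                    "cpg": cpg_ids,
                    "covariate": name,
                    "estimate": estimates[:, j],
                    "se": se[:, j],
                    "z": z[:, j],
                    "p": p[:, j],
                    "q": qvalues(p[:, j], method=q_method),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def decomposition_tables(
    part,
    boot: BootstrapDistribution,
    cpg_ids,
    covariate_names,
    q_method: str = "storey",
) -> dict:
    """Coefficient tables for Delta_k and B_k from a bootstrap run.

    The Wald ratios use a Student-t reference with ``n_boot - 1`` degrees
    of freedom: the bootstrap SE is itself an estimate with that many
    replicates behind it, and a plain normal reference is visibly
    anti-conservative in the far tails that genome-wide q-values depend
    on.  Returns ``{"delta": table, "b": table}``.
    """
    df = max(boot.n_boot - 1, 1)
    return {
        "delta": coefficient_table(
            part.Delta, boot.se_Delta, cpg_ids, covariate_names,
            q_method=q_method, reference="t", df=df,
        ),
        "b": coefficient_table(
            part.B, boot.se_B, cpg_ids, covariate_names,
            q_method=q_method, reference="t", df=df,
        ),
    }
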