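"""Synthetic cell-mixture methylation data with known ground truth.

The generator emulates what an Infinium-style beta matrix over a mixed
tissue looks like:

* cell-type mean profiles M (m x k') arise by recursive lineage
  splitting — a bimodal root profile is copied down a binary tree and,
  at every split, a disjoint block of differentially methylated loci is
  re-drawn independently for the two children, so sibling types differ
  exactly at their designated DMR loci;
* mixing proportions Omega (n x k') sit on the simplex, drawn from a
  Dirichlet whose log-concentrations are shifted linearly by the design,
  alpha_i = alpha0 * exp(X_i Gamma), giving an approximately linear
  covariate -> proportion map whose induced linear effect Gamma* can be
  recovered by Monte Carlo;
* sparse direct effects B (m x d), optionally projected onto the
  orthogonal complement of col(M) so that the direct effect lives
  exactly outside the cell-profile space;
* truncated-Gaussian measurement noise on the beta scale, with the final
  matrix clamped to [1e-6, 1 - 1e-6].

The module also builds the null scenarios used to calibrate the method:
joint phenotype permutation, and injection of *nonlinear* case effects on
the M-value scale (per-locus coefficients multiplied by independent
Gaussian scalars) after the linear case effect has been removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import BetaMatrix, DesignMatrix
from .inference import qvalues

__all__ = [
    "LineageTree",
    "MixtureGroundTruth",
    "balanced_tree",
    "simulate_reference_profiles",
    "simulate_mixture_dataset",
    "induced_proportion_effect",
    "permute_phenotype_null",
    "inject_nonlinear_effects",
    "beta_to_m",
    "m_to_beta",
    "default_scenario",
    "null_scenario_base",
    "reference_scenario",
]

CLAMP_EPS = 1e-6


@dataclass
class LineageTree:
    """Rooted binary tree over cell types.

    ``node`` is either a leaf name (str) or a dict
    ``{"split": [left, right], "n_dmr": r}``.  After profile simulation
    each internal node records the DMR locus indices assigned to its
    split in ``dmr_loci`` keyed by a path tuple.
    """

    node: object
    dmr_loci: dict = field(default_factory=dict)

    @property
    def leaves(self) -> list:
        out = []

        def walk(nd):
            if isinstance(nd, str):
                out.append(nd)
            else:
                for child in nd["split"]:
                    walk(child)

        walk(self.node)
        return out

    @property
    def n_types(self) -> int:
        return len(self.leaves)

    def splits(self) -> list:
        """(path, n_dmr) for every internal node, in preorder."""
        out = []

        def walk(nd, path):
            if isinstance(nd, str):
                return
            out.append((path, int(nd["n_dmr"])))
            for i, child in enumerate(nd["split"]):
                walk(child, path + (i,))

        walk(self.node, ())
        return out

    def separating_loci(self, leaf_a: str, leaf_b: str) -> set:
        """DMR loci of all splits on the path separating two leaves."""

        def path_to(nd, name, path):
            if isinstance(nd, str):
                return path if nd == name else None
            for i, child in enumerate(nd["split"]):
                found = path_to(child, name, path + (i,))
                if found is not None:
                    return found
            return None

        pa = path_to(self.node, leaf_a, ())
        pb = path_to(self.node, leaf_b, ())
        if pa is None or pb is None:
            raise ValueError("leaf not found in tree")
        common = 0
        for x, y in zip(pa, pb):
            if x != y:
                break
            common += 1
        loci = set()
        for depth in range(common, max(len(pa), len(pb))):
            for path in {pa[:depth], pb[:depth]}:
                if path in self.dmr_loci:
                    loci |= set(self.dmr_loci[path])
        return loci


@dataclass
class MixtureGroundTruth:
    """Everything the generator knows: Y = B_direct X^T + M Omega^T + E."""

    M: np.ndarray
    Omega: np.ndarray
    Gamma: np.ndarray
    Xi: np.ndarray
    B_direct: np.ndarray
    E: np.ndarray
    tree: LineageTree
    direct_loci: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def balanced_tree(n_types: int, n_dmr_per_split: int, names=None) -> LineageTree:
    """A balanced binary lineage over ``n_types`` leaves (power of two)."""
    if n_types < 1 or (n_types & (n_types - 1)) != 0:
        raise ValueError("balanced_tree needs a power-of-two number of types")
    if names is None:
        names = [f"type{i + 1}" for i in range(n_types)]

    def build(lo, hi):
        if hi - lo == 1:
            return names[lo]
        mid = (lo + hi) // 2
        return {"split": [build(lo, mid), build(mid, hi)], "n_dmr": n_dmr_per_split}

    return LineageTree(node=build(0, n_types))


def _bimodal_betas(size, rng, beta_params):
    """Draw beta values from a 50/50 mixture of a low and a high mode."""
    (a_lo, b_lo), (a_hi, b_hi) = beta_params
    lo = rng.beta(a_lo, b_lo, size=size)
    hi = rng.beta(a_hi, b_hi, size=size)
    pick = rng.random(size) < 0.5
    return np.where(pick, hi, lo)


def simulate_reference_profiles(
    m: int,
    tree_spec,
    beta_params=((2.0, 8.0), (8.0, 2.0)),
    seed: int = 0,
) -> tuple[np.ndarray, LineageTree]:
    """Cell-type mean-methylation profiles via recursive lineage splits.

    The root profile is bimodal on [0, 1] (most CpGs near 0 or near 1,
    as on real arrays).  Each split copies the parent profile to both
    children and re-draws its ``n_dmr`` designated loci independently per
    child; DMR blocks are disjoint across splits.  Returns M (m x k')
    with columns ordered as the tree leaves, and the tree annotated with
    the DMR locus indices per split.
    """
    tree = (
        tree_spec
        if isinstance(tree_spec, LineageTree)
        else LineageTree(node=tree_spec)
    )
    tree = LineageTree(node=tree.node)
    rng = np.random.default_rng(seed)
    splits = tree.splits()
    total_dmr = sum(r for _, r in splits)
    if total_dmr > m:
        raise ValueError(
            f"tree requires {total_dmr} DMR loci but only m={m} are available"
        )
    loci = rng.permutation(m)
    cursor = 0
    for path, r in splits:
        tree.dmr_loci[path] = np.sort(loci[cursor : cursor + r])
        cursor += r

    root_profile = _bimodal_betas(m, rng, beta_params)
    profiles = {}

    def descend(nd, profile, path):
        if isinstance(nd, str):
            profiles[nd] = profile
            return
        idx = tree.dmr_loci[path]
        for i, child in enumerate(nd["split"]):
            child_profile = profile.copy()
            child_profile[idx] = _bimodal_betas(idx.size, rng, beta_params)
            descend(child, child_profile, path + (i,))

    descend(tree.node, root_profile, ())
    M = np.column_stack([profiles[name] for name in tree.leaves])
    return M, tree


def _design_from_spec(n: int, X_spec, rng) -> DesignMatrix:
    """Build a design from covariate specs: ('binary', name, p) or
    ('continuous', name, mean, sd)."""
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for spec in X_spec:
        kind = spec[0]
        if kind == "binary":
            _, name, p = spec
            col = np.zeros(n)
            n_case = int(round(p * n))
            col[rng.choice(n, size=n_case, replace=False)] = 1.0
            cols.append(col)
        elif kind == "continuous":
            _, name, mean, sd = spec
            cols.append(rng.normal(mean, sd, size=n))
        else:
            raise ValueError(f"unknown covariate spec kind: {kind!r}")
        names.append(name)
    return DesignMatrix(values=np.column_stack(cols), column_names=names)


def simulate_mixture_dataset(
    M: np.ndarray,
    tree: LineageTree,
    n: int,
    X_spec,
    Gamma: np.ndarray,
    direct_spec: dict | None = None,
    noise_sd: float = 0.02,
    alpha0=None,
    noise_model: str = "truncated-gaussian",
    seed: int = 0,
) -> tuple[BetaMatrix, DesignMatrix, MixtureGroundTruth]:
    """Mixture-structured beta matrix with full ground truth.

    Proportions: row i of Omega ~ Dirichlet(alpha0 * exp(X_i Gamma)),
    which keeps rows on the simplex while the covariates shift the
    expected composition approximately linearly.  Direct effects: a
    sparse m x d matrix built from ``direct_spec``
    (``{"n_loci", "effect_size", "column", "orthogonalize"}``) and added
    as B X^T.  Noise: truncated Gaussian on the beta scale (or
    ``noise_model='beta'`` for beta-distributed noise around the signal).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    m, k_types = M.shape
    X = (
        X_spec
        if isinstance(X_spec, DesignMatrix)
        else _design_from_spec(n, X_spec, rng)
    )
    d = X.d
    Gamma = np.asarray(Gamma, dtype=float)
    if Gamma.shape != (d, k_types):
        raise ValueError(f"Gamma must be d x k' = {d} x {k_types}")
    if alpha0 is None:
        alpha0 = np.full(k_types, 10.0)
    alpha0 = np.asarray(alpha0, dtype=float)
    alpha = alpha0 * np.exp(X.values @ Gamma)
    if (alpha <= 0).any() or not np.isfinite(alpha).all():
        raise ValueError("Dirichlet concentration parameters must be positive")
    Omega = np.empty((n, k_types))
    for i in range(n):  # per-row concentrations
        Omega[i] = rng.dirichlet(alpha[i])
    mean_Omega = alpha / alpha.sum(axis=1, keepdims=True)
    Xi = Omega - mean_Omega

    B_direct = np.zeros((m, d))
    direct_loci = np.array([], dtype=int)
    if direct_spec is not None and direct_spec.get("n_loci", 0) > 0:
        n_loci = int(direct_spec["n_loci"])
        effect = float(direct_spec.get("effect_size", 0.05))
        col = int(direct_spec.get("column", 1))
        if not 1 <= col < d:
            raise ValueError("direct-effect column must be a non-intercept index")
        # keep planted loci clear of lineage DMRs so the two effect
        # classes are separable in truth
        dmr_all = set()
        for path, _ in tree.splits():
            dmr_all |= set(np.asarray(tree.dmr_loci.get(path, [])).tolist())
        candidates = np.setdiff1d(np.arange(m), np.fromiter(dmr_all, dtype=int, count=len(dmr_all)))
        if candidates.size < n_loci:
            raise ValueError("not enough non-DMR loci to place direct effects")
        direct_loci = np.sort(rng.choice(candidates, size=n_loci, replace=False))
        signs = rng.choice([-1.0, 1.0], size=n_loci)
        B_direct[direct_loci, col] = signs * effect
        if direct_spec.get("orthogonalize", True):
            # project the direct-effect column out of col(M)
            Qm, _ = np.linalg.qr(M)
            B_direct = B_direct - Qm @ (Qm.T @ B_direct)

    signal = B_direct @ X.values.T + M @ Omega.T
    if noise_sd == 0:
        E = np.zeros((m, n))
    elif noise_model == "truncated-gaussian":
        # inverse-CDF truncated normal, vectorised: keeps Y in (0, 1)
        lo = stats.norm.cdf((CLAMP_EPS - signal) / noise_sd)
        hi = stats.norm.cdf((1.0 - CLAMP_EPS - signal) / noise_sd)
        u = rng.random((m, n))
        E = noise_sd * stats.norm.ppf(lo + u * np.maximum(hi - lo, 1e-300))
    elif noise_model == "beta":
        mu = np.clip(signal, CLAMP_EPS, 1 - CLAMP_EPS)
        nu = np.maximum(mu * (1 - mu) / noise_sd**2 - 1.0, 2.0)
        E = rng.beta(mu * nu, (1 - mu) * nu) - signal
    else:
        raise ValueError(f"unknown noise model: {noise_model!r}")
    Y = np.clip(signal + E, CLAMP_EPS, 1.0 - CLAMP_EPS)

    truth = MixtureGroundTruth(
        M=M, Omega=Omega, Gamma=Gamma, Xi=Xi, B_direct=B_direct, E=Y - signal,
        tree=tree, direct_loci=direct_loci,
    )
    beta = BetaMatrix(values=Y)
    return beta, X, truth


def induced_proportion_effect(
    Gamma: np.ndarray,
    alpha0,
    X: DesignMatrix,
    n_draws: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo estimate of the induced linear effect Gamma* (d x k').

    The Dirichlet proportion model is only approximately linear in X;
    this computes E[Omega | X_i] for every design row (which is available
    in closed form for a Dirichlet: the normalised concentrations) and
    regresses it on X, giving the linear map the decomposition should
    recover as the mediated effect M Gamma*^T.
    """
    alpha0 = np.asarray(alpha0, dtype=float)
    alpha = alpha0 * np.exp(X.values @ np.asarray(Gamma, dtype=float))
    mean_Omega = alpha / alpha.sum(axis=1, keepdims=True)
    Gstar_T, *_ = np.linalg.lstsq(X.values, mean_Omega, rcond=None)
    return Gstar_T  # d x k'


def permute_phenotype_null(X: DesignMatrix, seed: int = 0) -> DesignMatrix:
    """Jointly permute the non-intercept design rows against the samples.

    Case status and covariates move together so the permuted design keeps
    its internal correlation structure while breaking any link with the
    methylation data.  The intercept column is untouched.
    """
    if X.d < 2:
        raise ValueError("permutation null needs at least one non-intercept column")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.n)
    values = X.values.copy()
    values[:, 1:] = values[perm, 1:]
    return DesignMatrix(values=values, column_names=list(X.column_names))


def beta_to_m(beta):
    """M-value (logit2 beta): m = log2(beta / (1 - beta)).

    Inputs at the boundary {0, 1} are clamped to [1e-6, 1 - 1e-6] with a
    warning before the transform.
    """
    beta = np.asarray(beta, dtype=float)
    if (beta <= 0).any() or (beta >= 1).any():
        warnings.warn(
            "beta values at or outside (0, 1) clamped before logit transform",
            RuntimeWarning,
            stacklevel=2,
        )
        beta = np.clip(beta, CLAMP_EPS, 1.0 - CLAMP_EPS)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m_value):
    """Inverse M-value transform: beta = 2^m / (2^m + 1)."""
    m_value = np.asarray(m_value, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m_value))


def _row_case_tests(M_values: np.ndarray, X: DesignMatrix, case_col: int):
    """Per-row OLS t-tests of the case coefficient on M-values."""
    n, d = X.values.shape
    XtX_inv = np.linalg.inv(X.values.T @ X.values)
    coef = M_values @ X.values @ XtX_inv.T  # m x d
    resid = M_values - coef @ X.values.T
    dof = n - d
    sigma2 = np.sum(resid**2, axis=1) / dof
    se = np.sqrt(sigma2 * XtX_inv[case_col, case_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[:, case_col] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(se == 0, 1.0, p)
    return coef[:, case_col], p


def inject_nonlinear_effects(
    Y: BetaMatrix,
    X: DesignMatrix,
    case_column: int = 1,
    q_threshold: float = 1e-4,
    effect_sd: float = 2.0,
    seed: int = 0,
) -> tuple[BetaMatrix, np.ndarray]:
    """Null-linear scenario with planted nonlinear case effects.

    Steps: (i) per-CpG case-coefficient t-tests on the M-value scale,
    unadjusted for cell mixture, with q-values; (ii) loci with
    q < ``q_threshold`` selected; (iii) the linear case effect removed on
    the beta scale by equalising case/control group means per locus (other
    covariate effects are left intact); (iv) at selected loci the original
    M-scale case coefficient, multiplied by an independent
    Normal(0, effect_sd) scalar, is re-applied on the M-scale to case
    samples; (v) back-transform and clamp.  The result has no linear case
    effect but sign-scrambled, magnitude-perturbed case effects at the
    selected loci.
    """
    case = X.values[:, case_column]
    uniq = np.unique(case)
    if case_column == 0 or uniq.size != 2 or not np.allclose(np.sort(uniq), [0.0, 1.0]):
        raise ValueError("case_column must index a binary (0/1) non-intercept covariate")
    if not 0.0 < q_threshold < 1.0:
        raise ValueError("q_threshold must be in (0, 1)")
    if effect_sd <= 0:
        raise ValueError("effect_sd must be positive")
    rng = np.random.default_rng(seed)

    M_values = beta_to_m(np.clip(Y.values, CLAMP_EPS, 1 - CLAMP_EPS))
    coef_m, p = _row_case_tests(M_values, X, case_column)
    q = qvalues(p, method="storey")
    selected = np.flatnonzero(q < q_threshold)

    # (iii) equalise raw case/control means on the beta scale
    is_case = case == 1.0
    beta = Y.values.copy()
    diff = beta[:, is_case].mean(axis=1) - beta[:, ~is_case].mean(axis=1)
    beta[:, is_case] -= diff[:, None]
    beta = np.clip(beta, CLAMP_EPS, 1.0 - CLAMP_EPS)

    if selected.size:
        scalars = rng.normal(0.0, effect_sd, size=selected.size)
        m_new = beta_to_m(beta[selected])
        m_new[:, is_case] += (coef_m[selected] * scalars)[:, None]
        beta[selected] = m_to_beta(m_new)
        beta = np.clip(beta, CLAMP_EPS, 1.0 - CLAMP_EPS)

    out = BetaMatrix(values=beta, cpg_ids=list(Y.cpg_ids), sample_ids=list(Y.sample_ids))
    return out, selected


def default_scenario(
    m: int = 20000,
    n: int = 200,
    n_types: int = 4,
    n_dmr_per_split: int = 300,
    case_fraction: float = 0.5,
    gamma_scale: float = 0.5,
    n_direct: int = 100,
    direct_effect: float = 0.08,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[BetaMatrix, DesignMatrix, MixtureGroundTruth]:
    """The package's reference simulation: a 4-type, 2-lineage tissue.

    A case/control phenotype shifts the composition (cases gain the
    types of one lineage at the expense of the other, log-concentration
    shift ``gamma_scale``) and additionally carries ``n_direct`` sparse
    direct-effect loci of size ``direct_effect`` on the beta scale,
    orthogonalised against the cell-profile space.
    """
    rng_seed = int(seed) % (2**31 - 2)
    tree = balanced_tree(n_types, n_dmr_per_split)
    M, tree = simulate_reference_profiles(m, tree, seed=rng_seed)
    half = n_types // 2
    gamma_case = np.concatenate(
        [np.full(half, gamma_scale), np.full(n_types - half, -gamma_scale)]
    )
    Gamma = np.vstack([np.zeros(n_types), gamma_case])
    return simulate_mixture_dataset(
        M,
        tree,
        n=n,
        X_spec=[("binary", "case", case_fraction)],
        Gamma=Gamma,
        direct_spec={
            "n_loci": n_direct,
            "effect_size": direct_effect,
            "column": 1,
            "orthogonalize": True,
        },
        noise_sd=noise_sd,
        seed=rng_seed + 1,
    )


def reference_scenario(
    m: int = 2000,
    n_per_type: int = 12,
    n_types: int = 4,
    n_dmr_per_split: int = 60,
    purity: float = 50.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[BetaMatrix, DesignMatrix, MixtureGroundTruth]:
    """A purified-cell-type reference design.

    Emulates a leukocyte reference dataset: each sample is a nearly pure
    preparation of one cell type (Dirichlet concentration ``purity`` on
    the own type, 0.5 elsewhere), and the design codes cell type as a
    categorical factor with the first type as reference.  The
    non-intercept columns of Delta_k then estimate per-type contrasts
    against the reference type, the objects whose hierarchical clustering
    should recover the simulated lineage tree.
    """
    rng_seed = int(seed) % (2**31 - 2)
    tree = balanced_tree(n_types, n_dmr_per_split)
    M, tree = simulate_reference_profiles(m, tree, seed=rng_seed)
    names = tree.leaves
    n = n_per_type * n_types
    # categorical design: intercept + indicator per non-reference type
    X_values = np.ones((n, n_types))
    type_of = np.repeat(np.arange(n_types), n_per_type)
    for j in range(1, n_types):
        X_values[:, j] = (type_of == j).astype(float)
    X = DesignMatrix(
        values=X_values,
        column_names=["(Intercept)"] + [names[j] for j in range(1, n_types)],
    )
    # Gamma chosen so each sample's Dirichlet concentrates on its own type
    base = np.full(n_types, 0.5)
    base[0] = purity  # reference type concentration for intercept-only rows
    Gamma = np.zeros((n_types, n_types))
    for j in range(1, n_types):
        target = np.full(n_types, 0.5)
        target[j] = purity
        Gamma[j] = np.log(target / base)
    return simulate_mixture_dataset(
        M, tree, n=n, X_spec=X, Gamma=Gamma, direct_spec=None,
        noise_sd=noise_sd, alpha0=base, seed=rng_seed + 1,
    )


def null_scenario_base(
    m: int = 20000,
    n: int = 180,
    seed: int = 0,
    **overrides,
) -> tuple[BetaMatrix, DesignMatrix, MixtureGroundTruth]:
    """Base dataset for the null-scenario calibration studies.

    Emulates an epidemiological blood case/control array: a real but
    moderate case effect on cell composition (log-concentration shift
    0.2, which puts roughly 1-3% of loci past q < 1e-4 in an unadjusted
    M-value case analysis, in line with a typical blood case/control
    study of this size) and no direct effects, so any direct-effect
    signal present after permutation or injection is by construction
    artificial.  Keyword overrides pass through to ``default_scenario``.
    """
    params = dict(gamma_scale=0.2, n_direct=0)
    params.update(overrides)
    return default_scenario(m=m, n=n, seed=seed, **params)
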