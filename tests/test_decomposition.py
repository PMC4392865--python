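"""Total-effect regression and SVD partition: oracles and invariants."""

import numpy as np
import pytest

from refcellfree import (
    BetaMatrix,
    DesignMatrix,
    expansion_term,
    fit_total_effect,
    partition_effect,
    svd_expansion,
)


def _random_instance(rng, m=8, n=10, d=3, scale=0.1):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, d - 1))])
    Y = np.clip(0.5 + scale * rng.normal(size=(m, n)), 0.01, 0.99)
    return (
        BetaMatrix(values=Y),
        DesignMatrix(values=X),
    )


class TestFitTotalEffect:
    def test_intercept_only_is_row_mean(self):
        Y = BetaMatrix(values=np.array([[0.2, 0.4, 0.6]]))
        X = DesignMatrix(values=np.ones((3, 1)))
        fit = fit_total_effect(Y, X)
        assert fit.A == pytest.approx(np.array([[0.4]]))
        assert fit.R == pytest.approx(np.array([[-0.2, 0.0, 0.2]]), abs=1e-12)

    def test_exact_fit_recovers_coefficients(self, rng):
        n, d, m = 9, 2, 6
        X = DesignMatrix(values=np.column_stack([np.ones(n), rng.normal(size=n)]))
        A0 = rng.uniform(-0.1, 0.1, size=(m, d))
        A0[:, 0] += 0.5
        Y = BetaMatrix(values=np.clip(A0 @ X.values.T, 0, 1))
        fit = fit_total_effect(Y, X)
        assert np.abs(fit.A - A0).max() < 1e-10
        assert np.abs(fit.R).max() < 1e-10

    def test_matches_pseudoinverse_oracle(self, rng):
        X = DesignMatrix(values=np.column_stack([np.ones(4), rng.normal(size=4)]))
        Y = BetaMatrix(values=rng.uniform(0.1, 0.9, size=(5, 4)))
        fit = fit_total_effect(Y, X)
        A_oracle = Y.values @ np.linalg.pinv(X.values).T
        assert np.abs(fit.A - A_oracle).max() < 1e-10

    def test_residuals_orthogonal_to_design(self, small_dataset):
        Y, X = small_dataset
        fit = fit_total_effect(Y, X)
        scale = np.abs(Y.values).max()
        assert np.abs(fit.R @ X.values).max() <= 1e-8 * scale

    def test_missing_values_mean_imputed(self, small_design):
        vals = np.full((3, 12), 0.5)
        vals[1, 3] = np.nan
        fit = fit_total_effect(BetaMatrix(values=vals), small_design)
        # constant rows after imputation: intercept 0.5, no residual
        assert fit.A[:, 0] == pytest.approx([0.5] * 3)
        assert np.abs(fit.R).max() < 1e-12

    def test_all_missing_row_rejected(self, small_design):
        vals = np.full((2, 12), 0.5)
        vals[0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_total_effect(BetaMatrix(values=vals), small_design)

    def test_collinear_design_names_columns(self):
        n = 8
        x = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(values=X, column_names=["(Intercept)", "a", "b"])

    def test_too_few_samples_rejected(self, rng):
        X = DesignMatrix(values=np.column_stack([np.ones(3), rng.normal(size=3)]))
        Y = BetaMatrix(values=rng.uniform(0.2, 0.8, size=(4, 3)))
        with pytest.raises(ValueError, match="n >= d"):
            fit_total_effect(Y, X)


class TestSvdExpansion:
    def test_zero_effect_gives_zero_vstar(self, rng):
        # Y constant across samples given centered design -> A has only the
        # intercept; here remove it too by building [A R] with A = 0.
        from refcellfree.decomposition import TotalEffectFit

        R = rng.normal(size=(6, 8))
        fit = TotalEffectFit(
            A=np.zeros((6, 2)), R=R, design=None, cpg_ids=list("abcdef"),
            covariate_names=["(Intercept)", "x"],
        )
        dec = svd_expansion(fit)
        assert np.abs(dec.Vstar).max() < 1e-12
        for k in range(dec.rank + 1):
            assert np.abs(partition_effect(dec, k).Delta).max() < 1e-12

    def test_reconstruction_identity(self, small_decomposition):
        dec = small_decomposition
        recon = (dec.U * dec.lambdas) @ dec.Vstar.T
        assert np.abs(recon - dec.A).max() <= 1e-8 * np.linalg.norm(dec.A)

    def test_singular_values_match_eigen_oracle(self, rng):
        Y, X = _random_instance(rng, m=6, n=7, d=3)
        fit = fit_total_effect(Y, X)
        dec = svd_expansion(fit)
        concat = np.hstack([fit.A, fit.R])
        eigs = np.sort(np.linalg.eigvalsh(concat @ concat.T))[::-1][: dec.rank]
        assert np.abs(dec.lambdas**2 - eigs).max() <= 1e-8 * eigs[0]

    def test_orthonormal_left_vectors(self, small_decomposition):
        dec = small_decomposition
        gram = dec.U.T @ dec.U
        assert np.abs(gram - np.eye(dec.rank)).max() < 1e-8

    def test_zero_matrix_rejected(self):
        from refcellfree.decomposition import TotalEffectFit

        fit = TotalEffectFit(
            A=np.zeros((4, 2)), R=np.zeros((4, 5)), design=None,
            cpg_ids=list("abcd"), covariate_names=["(Intercept)", "x"],
        )
        with pytest.raises(ValueError, match="degenerate"):
            svd_expansion(fit)


class TestPartition:
    def test_k_zero_and_k_rank(self, small_decomposition):
        dec = small_decomposition
        p0 = partition_effect(dec, 0)
        assert np.abs(p0.Delta).max() == 0
        assert p0.B == pytest.approx(dec.A)
        pr = partition_effect(dec, dec.rank)
        norm = np.linalg.norm(dec.A)
        assert np.abs(pr.Delta - dec.A).max() <= 1e-10 * norm
        assert np.abs(pr.B).max() <= 1e-10 * norm

    def test_k_one_equals_outer_product_oracle(self, rng):
        # rank-2 construction with well separated singular values 5 and 2
        m, d, n = 7, 2, 6
        u = np.linalg.qr(rng.normal(size=(m, 2)))[0]
        v = np.linalg.qr(rng.normal(size=(d + n, 2)))[0]
        concat = 5.0 * np.outer(u[:, 0], v[:, 0]) + 2.0 * np.outer(u[:, 1], v[:, 1])
        from refcellfree.decomposition import TotalEffectFit

        fit = TotalEffectFit(
            A=concat[:, :d], R=concat[:, d:], design=None,
            cpg_ids=[f"c{i}" for i in range(m)],
            covariate_names=["(Intercept)", "x"],
        )
        dec = svd_expansion(fit)
        part = partition_effect(dec, 1)
        oracle = 5.0 * np.outer(u[:, 0], v[:d, 0])
        # sign of the SVD pair is arbitrary but the outer product is not
        assert np.abs(np.abs(part.Delta) - np.abs(oracle)).max() < 1e-10
        assert part.Delta == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("k", [0, 2, 5])
    def test_conservation_and_orthogonality(self, small_decomposition, k):
        dec = small_decomposition
        part = partition_effect(dec, k)
        norm = np.linalg.norm(dec.A)
        assert np.abs(part.Delta + part.B - dec.A).max() <= 1e-10 * norm
        assert np.abs(part.Delta.T @ part.B).max() <= 1e-8 * norm**2

    def test_out_of_range_k(self, small_decomposition):
        with pytest.raises(ValueError, match="valid range"):
            partition_effect(small_decomposition, -1)
        with pytest.raises(ValueError, match="valid range"):
            partition_effect(small_decomposition, small_decomposition.rank + 1)

    def test_noiseless_mixture_fully_captured(self, rng):
        # Y = M Omega^T exactly: the whole effect is cell composition,
        # so B vanishes once k reaches the mixture rank.
        m, n, kp = 40, 15, 3
        M = rng.uniform(0.1, 0.9, size=(m, kp))
        Omega = rng.dirichlet(np.ones(kp), size=n)
        Y = BetaMatrix(values=np.clip(M @ Omega.T, 0, 1))
        X = DesignMatrix(
            values=np.column_stack([np.ones(n), rng.normal(size=n)])
        )
        fit = fit_total_effect(Y, X)
        dec = svd_expansion(fit)
        part = partition_effect(dec, min(kp, dec.rank))
        assert np.linalg.norm(part.B) <= 1e-6 * np.linalg.norm(fit.A)

    def test_invariant_to_sign_flips_and_reordering(self, small_decomposition):
        import copy

        dec = small_decomposition
        k = 3
        ref = partition_effect(dec, k).Delta
        flipped = copy.deepcopy(dec)
        flipped.U[:, 1] *= -1
        flipped.Vstar[:, 1] *= -1
        assert partition_effect(flipped, k).Delta == pytest.approx(ref)
        # reorder within the first k block (degenerate-safe: swap cols 0,1
        # along with their singular values)
        swapped = copy.deepcopy(dec)
        order = [1, 0] + list(range(2, dec.rank))
        swapped.U = swapped.U[:, order]
        swapped.Vstar = swapped.Vstar[:, order]
        swapped.lambdas = swapped.lambdas[order]
        assert partition_effect(swapped, k).Delta == pytest.approx(ref)

    def test_near_degenerate_boundary_warns(self, rng):
        from refcellfree.decomposition import TotalEffectFit

        m, d, n = 10, 2, 8
        u = np.linalg.qr(rng.normal(size=(m, 2)))[0]
        v = np.linalg.qr(rng.normal(size=(d + n, 2)))[0]
        concat = 3.0 * np.outer(u[:, 0], v[:, 0]) + 2.9999 * np.outer(u[:, 1], v[:, 1])
        fit = TotalEffectFit(
            A=concat[:, :d], R=concat[:, d:], design=None,
            cpg_ids=[f"c{i}" for i in range(m)],
            covariate_names=["(Intercept)", "x"],
        )
        dec = svd_expansion(fit)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            partition_effect(dec, 1)


class TestExpansionTerm:
    def test_terms_sum_to_A(self, small_decomposition):
        dec = small_decomposition
        total = sum(expansion_term(dec, j) for j in range(1, dec.rank + 1))
        assert np.abs(total - dec.A).max() <= 1e-8 * np.linalg.norm(dec.A)

    def test_each_term_rank_one(self, small_decomposition):
        dec = small_decomposition
        for j in (1, dec.rank):
            s = np.linalg.svd(expansion_term(dec, j), compute_uv=False)
            assert s[1] <= 1e-10 * s[0]

    def test_term_is_partition_difference(self, small_decomposition):
        dec = small_decomposition
        for j in (1, 2, 4):
            diff = partition_effect(dec, j).Delta - partition_effect(dec, j - 1).Delta
            assert expansion_term(dec, j) == pytest.approx(diff, abs=1e-12)

    def test_out_of_range_term(self, small_decomposition):
        with pytest.raises(ValueError):
            expansion_term(small_decomposition, 0)


def test_brute_force_oracle_equivalence():
    """Partition equals an independent full-SVD outer-product summation."""
    rng = np.random.default_rng(99)
    for _ in range(5):
        X = np.column_stack([np.ones(5), rng.normal(size=(5, 1))])
        Y = rng.uniform(0.1, 0.9, size=(8, 5))
        Xd = DesignMatrix(values=X)
        fit = fit_total_effect(BetaMatrix(values=Y), Xd)
        dec = svd_expansion(fit)
        # brute force: full dense SVD, explicit outer-product sums
        U, lam, Vt = np.linalg.svd(np.hstack([fit.A, fit.R]), full_matrices=True)
        for k in range(1, dec.rank + 1):
            delta_bf = sum(
                lam[j] * np.outer(U[:, j], Vt[j, :2]) for j in range(k)
            )
            assert np.abs(partition_effect(dec, k).Delta - delta_bf).max() < 1e-9
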