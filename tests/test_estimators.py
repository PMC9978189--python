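"""Network estimators: correlation, l1, sparse+low-rank, and AM-PC."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from modnet.estimators import (
    AmpcConfig,
    ConstantColumnError,
    TimeSeries,
    ampc_estimate,
    ampc_objective,
    ampc_update_F,
    ampc_update_W,
    estimate_network,
    mpc_network,
    mpc_objective,
    pearson_network,
    remove_negative_edges,
    sparse_pc_network,
    sparse_pc_objective,
)
from modnet.graph import (
    build_laplacian,
    connected_components,
    count_zero_eigenvalues,
    pairwise_rowdistance_matrix,
    spectrum,
)
from modnet.synthetic import ModularCohortSpec, generate_scan
from tests.oracles import (
    condat_vu_sparse_lowrank,
    ista_sparse_regression,
    pearson_textbook,
    qp_wstep,
)


class TestTimeSeries:
    def test_columns_standardized(self, rng):
        ts = TimeSeries.from_raw(rng.standard_normal((25, 4)) * 7 + 3)
        assert np.all(np.abs(ts.data.mean(axis=0)) < 1e-10)
        np.testing.assert_allclose(np.linalg.norm(ts.data, axis=0), 1.0, atol=1e-10)
        A = ts.correlation()
        np.testing.assert_allclose(np.diag(A), 1.0)
        assert np.all(np.abs(A) <= 1.0)

    def test_constant_column_raises_with_roi_name(self, rng):
        raw = rng.standard_normal((20, 3))
        raw[:, 1] = 4.2
        with pytest.raises(ConstantColumnError, match="colB"):
            TimeSeries.from_raw(raw, ["colA", "colB", "colC"])

    def test_constant_column_droppable(self, rng):
        raw = rng.standard_normal((20, 3))
        raw[:, 1] = 4.2
        with pytest.warns(UserWarning, match="colB"):
            ts = TimeSeries.from_raw(raw, ["colA", "colB", "colC"], on_constant="drop")
        assert ts.roi_names == ("colA", "colC")
        assert ts.n == 2


class TestPearsonNetwork:
    def test_identical_columns_have_unit_weight(self):
        x = np.arange(10.0)
        ts = TimeSeries.from_raw(np.column_stack([x, x, -x]))
        W = pearson_network(ts)
        assert W[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert W[0, 2] == pytest.approx(-1.0, abs=1e-12)
        np.testing.assert_array_equal(np.diag(W), 0.0)

    def test_matches_textbook_formula(self, rng):
        raw = rng.standard_normal((20, 5)) * 3 + 1
        W = pearson_network(TimeSeries.from_raw(raw))
        expected = pearson_textbook(raw)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(W, expected, atol=1e-12)


class TestRemoveNegativeEdges:
    def test_all_negative_becomes_zero(self):
        W = np.array([[0.0, -0.3], [-0.3, 0.0]])
        np.testing.assert_array_equal(remove_negative_edges(W), np.zeros((2, 2)))

    def test_mixed_signs(self, rng):
        W = rng.standard_normal((6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        out = remove_negative_edges(W)
        np.testing.assert_array_equal(out[W > 0], W[W > 0])
        assert np.all(out[W < 0] == 0.0)
        np.testing.assert_array_equal(out, out.T)


class TestSparsePcNetwork:
    def test_lam_zero_orthonormal_design_recovers_correlations(self, rng):
        # orthonormal columns: regression of x_j on the others gives X^T x_j
        Q, _ = np.linalg.qr(rng.standard_normal((12, 4)))
        ts = TimeSeries(data=Q, roi_names=tuple("abcd"))
        W = sparse_pc_network(ts, lam=0.0)
        A = Q.T @ Q
        np.fill_diagonal(A, 0.0)
        np.testing.assert_allclose(W, A, atol=1e-8)

    def test_huge_lambda_gives_empty_network(self, small_ts):
        lam = 10.0 * small_ts.m * np.abs(small_ts.correlation()).max()
        W = sparse_pc_network(small_ts, lam=lam)
        np.testing.assert_array_equal(W, np.zeros_like(W))

    def test_objective_matches_ista_oracle(self, small_ts):
        lam = 0.5
        W = sparse_pc_network(small_ts, lam=lam)
        W_ref = ista_sparse_regression(small_ts.data, lam)
        obj = sparse_pc_objective(small_ts, W, lam)
        obj_ref = sparse_pc_objective(small_ts, (W_ref + W_ref.T) / 2, lam)
        # compare pre-symmetrization objectives too: both solvers address
        # the same column-wise problem
        assert obj == pytest.approx(obj_ref, rel=1e-6, abs=1e-6)

    def test_soft_threshold_variant_closed_form(self, small_ts):
        lam = 0.4
        W = sparse_pc_network(small_ts, lam=lam, variant="soft-threshold")
        A = small_ts.correlation()
        expected = np.sign(A) * np.maximum(np.abs(A) - lam / 2.0, 0.0)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_negative_lambda_rejected(self, small_ts):
        with pytest.raises(ValueError):
            sparse_pc_network(small_ts, lam=-0.1)


@pytest.fixture(scope="module")
def ts5():
    rng = np.random.default_rng(5)
    return TimeSeries.from_raw(rng.standard_normal((30, 5)))


class TestMpcNetwork:
    def test_no_trace_penalty_coincides_with_sparse_pc(self, ts5):
        lam = 0.5
        W_mpc = mpc_network(ts5, lam1=lam, lam2=0.0)
        W_sparse = sparse_pc_network(ts5, lam=lam)
        obj_mpc = sparse_pc_objective(ts5, W_mpc, lam)
        obj_sparse = sparse_pc_objective(ts5, W_sparse, lam)
        assert obj_mpc == pytest.approx(obj_sparse, rel=1e-4)

    def test_unpenalized_square_design_returns_identity(self, rng):
        # square invertible design, diagonal unconstrained: ||X - XW||^2 has
        # the exact minimizer W = I with objective 0
        raw = rng.standard_normal((6, 5))
        ts = TimeSeries.from_raw(raw)
        X5 = ts.data  # 6x5 centered -> effective rank 5, X full column rank
        W = mpc_network(ts, lam1=0.0, lam2=0.0, constrain_diagonal=False, tol=1e-12)
        assert mpc_objective(ts, W, 0.0, 0.0) == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(X5 @ W, X5, atol=1e-6)

    def test_objective_matches_primal_dual_oracle(self, ts5):
        lam1 = lam2 = 0.5
        W = mpc_network(ts5, lam1=lam1, lam2=lam2)
        W_ref = condat_vu_sparse_lowrank(ts5.data, lam1, lam2)
        W_ref = (W_ref + W_ref.T) / 2
        np.fill_diagonal(W_ref, 0.0)
        obj = mpc_objective(ts5, W, lam1, lam2)
        obj_ref = mpc_objective(ts5, W_ref, lam1, lam2)
        assert obj == pytest.approx(obj_ref, rel=1e-4)

    def test_negative_penalties_rejected(self, ts5):
        with pytest.raises(ValueError):
            mpc_network(ts5, lam1=-1.0, lam2=0.0)


class TestAmpcUpdateF:
    def test_block_diagonal_reaches_zero_trace(self, rng):
        from scipy.linalg import block_diag

        blocks = [np.ones((3, 3)) for _ in range(3)]
        W = block_diag(*blocks)
        np.fill_diagonal(W, 0.0)
        for normalized in (False, True):
            F = ampc_update_F(W, k=3, normalized=normalized)
            L = build_laplacian(W, normalized=normalized)
            assert np.trace(F.T @ L @ F) == pytest.approx(0.0, abs=1e-10)

    def test_full_basis_recovers_total_trace(self, rng):
        W = np.abs(rng.standard_normal((6, 6)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        L = build_laplacian(W)
        s = spectrum(L)
        assert np.sum(s.eigenvalues) == pytest.approx(np.trace(L), abs=1e-8)

    def test_ky_fan_minimality_over_random_competitors(self, rng):
        W = np.abs(rng.standard_normal((12, 12)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        L = build_laplacian(W)
        F = ampc_update_F(W, k=3, normalized=False)
        best = np.trace(F.T @ L @ F)
        for _ in range(1000):
            G, _ = np.linalg.qr(rng.standard_normal((12, 3)))
            assert best <= np.trace(G.T @ L @ G) + 1e-10

    def test_k_not_less_than_n_rejected(self):
        W = np.zeros((4, 4))
        with pytest.raises(ValueError):
            ampc_update_F(W, k=4)


class TestAmpcUpdateW:
    def test_penalty_free_case_is_clipped_correlation(self, rng):
        A = rng.uniform(-1, 1, (5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        W = ampc_update_W(A, np.zeros_like(A), alpha=0.0, lam=0.0)
        expected = np.maximum(A, 0.0)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_scalar_case_closed_form(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        W = ampc_update_W(A, np.zeros((2, 2)), alpha=1.0, lam=0.4)
        assert W[0, 1] == pytest.approx(0.3, abs=1e-12)
        # cross-check the one-variable QP with the generic solver
        W_ref = qp_wstep(A, np.zeros((2, 2)), alpha=1.0, lam=0.4)
        assert W_ref[0, 1] == pytest.approx(0.3, abs=1e-8)

    def test_matches_generic_qp_solver(self):
        """Closed form equals a generic nonnegative-QP solve entrywise on
        random instances (n <= 10)."""
        rng = np.random.default_rng(99)
        for trial in range(20):
            n = int(rng.integers(3, 11))
            A = rng.uniform(-1, 1, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            F = rng.standard_normal((n, int(rng.integers(1, n))))
            fdist = pairwise_rowdistance_matrix(F)
            alpha = float(rng.uniform(0, 3))
            lam = float(rng.uniform(0, 1))
            W = ampc_update_W(A, fdist, alpha, lam)
            W_ref = qp_wstep(A, fdist, alpha, lam)
            np.testing.assert_allclose(W, W_ref, atol=1e-6)

    def test_sparsity_monotone_in_penalties(self, rng):
        A = rng.uniform(-1, 1, (8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        fdist = pairwise_rowdistance_matrix(rng.standard_normal((8, 3)))
        lam_grid = [0.0, 0.1, 0.3, 0.6, 1.0, 2.0]
        nnz_lam = [
            np.count_nonzero(ampc_update_W(A, fdist, 0.5, lam)) for lam in lam_grid
        ]
        assert nnz_lam == sorted(nnz_lam, reverse=True)
        alpha_grid = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
        nnz_alpha = [
            np.count_nonzero(ampc_update_W(A, fdist, a, 0.1)) for a in alpha_grid
        ]
        assert nnz_alpha == sorted(nnz_alpha, reverse=True)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ampc_update_W(np.eye(3), np.zeros((4, 4)), 1.0, 0.0)


class TestAmpcEstimate:
    def test_recovers_planted_modules(self):
        spec = ModularCohortSpec(
            n_rois=24, k_true=4, n_subjects_per_class=(2, 2), seed=3
        )
        ts, truth = generate_scan(spec, 0, np.random.default_rng(3))
        res = ampc_estimate(ts, AmpcConfig(k=4, lam=2**-5))
        assert res.converged
        part = connected_components(res.W)
        assert adjusted_rand_score(truth.labels, part.labels) >= 0.9

    def test_degenerate_settings_reduce_to_clipped_pc(self, small_ts):
        cfg = AmpcConfig(k=2, lam=0.0, alpha0=1e-12, max_outer_iters=1)
        res = ampc_estimate(small_ts, cfg)
        expected = np.maximum(small_ts.correlation(), 0.0)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(res.W, expected, atol=1e-9)

    @pytest.mark.parametrize("normalized", [False, True])
    def test_objective_monotone_within_each_iteration(self, normalized):
        spec = ModularCohortSpec(
            n_rois=20, k_true=4, n_subjects_per_class=(2, 2), seed=4
        )
        ts, _ = generate_scan(spec, 1, np.random.default_rng(4))
        cfg = AmpcConfig(k=4, lam=0.05, normalized_laplacian=normalized)
        res = ampc_estimate(ts, cfg)
        for it in res.iterations:
            assert it.obj_after_F <= it.obj_before + 1e-9
            assert it.obj_after_W <= it.obj_after_F + 1e-9

    def test_objective_monotone_across_iterations_unnormalized(self):
        """With the unnormalized Laplacian the full alternating chain is
        non-increasing whenever alpha is unchanged between iterations."""
        spec = ModularCohortSpec(
            n_rois=20, k_true=4, n_subjects_per_class=(2, 2), seed=5
        )
        ts, _ = generate_scan(spec, 0, np.random.default_rng(5))
        res = ampc_estimate(ts, AmpcConfig(k=4, lam=0.05, normalized_laplacian=False))
        its = res.iterations
        for prev, cur in zip(its, its[1:]):
            if prev.alpha == cur.alpha:
                assert cur.obj_after_F <= prev.obj_after_W + 1e-9

    def test_converged_component_count_consistency(self):
        spec = ModularCohortSpec(
            n_rois=30, k_true=5, n_subjects_per_class=(2, 2), seed=6
        )
        ts, _ = generate_scan(spec, 0, np.random.default_rng(6))
        cfg = AmpcConfig(k=5, lam=2**-5)
        res = ampc_estimate(ts, cfg)
        assert res.converged
        L = build_laplacian(res.W, normalized=True)
        assert count_zero_eigenvalues(spectrum(L)) == 5
        assert connected_components(res.W).k_observed == 5
        assert res.W.min() >= 0.0
        np.testing.assert_array_equal(np.diag(res.W), 0.0)
        np.testing.assert_allclose(res.W, res.W.T, atol=1e-12)

    def test_nonconvergence_reported_not_raised(self, small_ts):
        cfg = AmpcConfig(k=2, lam=0.0, alpha0=1e-8, max_outer_iters=2)
        res = ampc_estimate(small_ts, cfg)
        assert res.converged in (False, True)  # never raises
        assert len(res.iterations) <= 2

    def test_k_too_large_rejected(self, small_ts):
        with pytest.raises(ValueError):
            ampc_estimate(small_ts, AmpcConfig(k=small_ts.n))


class TestDispatch:
    @pytest.mark.parametrize("method", ["pc", "pc+", "sparse-pc+", "am-pc"])
    def test_known_methods_produce_valid_networks(self, small_ts, method):
        params = {"lam": 0.2} if "sparse" in method else {}
        if method == "am-pc":
            params = {"k": 2, "lam": 0.1}
        W = estimate_network(small_ts, method, **params)
        np.testing.assert_allclose(W, W.T, atol=1e-10)
        np.testing.assert_array_equal(np.diag(W), 0.0)
        if method.endswith("+") or method == "am-pc":
            assert W.min() >= 0.0

    def test_unknown_method_rejected(self, small_ts):
        with pytest.raises(ValueError, match="unknown method"):
            estimate_network(small_ts, "ridge")
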