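"""Row-action solvers: projection steps, ART, Kaczmarz and the PB scheme."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import blockart as ba
from blockart.errors import DegenerateRowError


class TestArtStep:
    def test_point_on_hyperplane_is_fixed(self):
        x = np.array([0.5, 0.5])
        a = np.array([1.0, 1.0])
        out = ba.art_step(x, a, 1.0, lam=1.7)
        np.testing.assert_allclose(out, x)

    def test_orthogonal_projection_onto_axis(self):
        out = ba.art_step(np.zeros(2), np.array([1.0, 0.0]), 1.0, lam=1.0)
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_half_relaxed_step(self):
        out = ba.art_step(np.zeros(2), np.array([1.0, 1.0]), 2.0, lam=0.5)
        np.testing.assert_allclose(out, [0.5, 0.5])
        assert out @ np.array([1.0, 1.0]) == pytest.approx(1.0)

    def test_sparse_row_accepted(self):
        row = sp.csr_matrix(np.array([[0.0, 2.0, 0.0]]))
        out = ba.art_step(np.zeros(3), row, 4.0, lam=1.0)
        np.testing.assert_allclose(out, [0.0, 2.0, 0.0])

    def test_zero_row_raises(self):
        with pytest.raises(DegenerateRowError):
            ba.art_step(np.zeros(2), np.zeros(2), 1.0, lam=1.0)

    @given(
        hnp.arrays(np.float64, 4, elements=st.floats(-5, 5)),
        hnp.arrays(np.float64, 4, elements=st.floats(-3, 3)),
        st.floats(-4, 4),
    )
    def test_unit_relaxation_lands_on_hyperplane(self, x, a, p):
        """With lam=1 the updated point satisfies a . x' = p exactly."""
        if np.linalg.norm(a) < 1e-3:
            return
        out = ba.art_step(x, a, p, lam=1.0)
        assert a @ out == pytest.approx(p, abs=1e-10)
        np.testing.assert_allclose(out, ba.kaczmarz_step(x, a, p))


class TestConstrain:
    def test_clamps_negatives(self):
        np.testing.assert_array_equal(ba.constrain(np.array([-1.0, 2.0, 0.0])), [0.0, 2.0, 0.0])

    @given(hnp.arrays(np.float64, 6, elements=st.floats(-10, 10)))
    def test_idempotent_and_identity_on_feasible(self, x):
        once = ba.constrain(x)
        np.testing.assert_array_equal(ba.constrain(once), once)
        if np.all(x >= 0):
            np.testing.assert_array_equal(once, x)


class TestSolverConfig:
    def test_warns_outside_convergence_interval(self):
        with pytest.warns(UserWarning, match="0 < lam < 2"):
            ba.SolverConfig(lam=2.5)

    def test_accepts_interior_lambda(self, recwarn):
        ba.SolverConfig(lam=1.5)
        assert not recwarn.list

    def test_rejects_bad_enums(self):
        with pytest.raises(ValueError):
            ba.SolverConfig(constraint="clip")
        with pytest.raises(ValueError):
            ba.SolverConfig(constraint_timing="sometimes")


class TestArtSolve:
    def test_orthogonal_two_by_two(self):
        A = sp.csr_matrix(np.eye(2))
        b = np.array([1.0, 1.0])
        cfg = ba.SolverConfig(lam=1.0, constraint="none", max_iterations=2)
        res = ba.art_solve(A, b, cfg)
        np.testing.assert_allclose(res.x, [1.0, 1.0], atol=1e-8)
        assert res.iterations_run <= 2

    def test_consistent_system_reaches_least_squares_solution(self):
        """On a consistent 5x4 system ART converges to the dense-lstsq oracle."""
        local = np.random.default_rng(11)
        A = sp.csr_matrix(local.uniform(0.1, 1.0, size=(5, 4)))
        x_true = local.uniform(0.0, 2.0, size=4)
        b = A @ x_true
        oracle = np.linalg.lstsq(A.todense(), b, rcond=None)[0]
        cfg = ba.SolverConfig(lam=1.0, constraint="none", max_iterations=20000,
                              stop_delta=1e-7)
        res = ba.art_solve(A, b, cfg, truth=x_true)
        assert ba.max_abs_error(res.x, np.asarray(oracle).ravel()) < 1e-6
        assert ba.max_abs_error(res.x, x_true) < 1e-6

    def test_stop_delta_without_truth_rejected(self, small_system):
        A, b, _, _ = small_system
        cfg = ba.SolverConfig(stop_delta=0.1)
        with pytest.raises(ValueError):
            ba.art_solve(A, b, cfg)

    def test_constrained_result_is_non_negative(self, small_system):
        A, b, truth, _ = small_system
        cfg = ba.SolverConfig(lam=1.5, constraint="nonneg", max_iterations=50)
        res = ba.art_solve(A, b, cfg, truth=truth)
        assert np.all(res.x >= 0)
        assert len(res.history) == res.iterations_run

    def test_matches_kaczmarz_at_unit_relaxation(self, small_system):
        """lam=1, no constraint: the ART path reproduces plain Kaczmarz."""
        A, b, truth, _ = small_system
        cfg = ba.SolverConfig(lam=1.0, constraint="none", max_iterations=7)
        res_art = ba.art_solve(A, b, cfg, truth=truth)
        res_kz = ba.kaczmarz_solve(A, b, max_iterations=7, truth=truth)
        np.testing.assert_allclose(res_art.x, res_kz.x, rtol=1e-12, atol=1e-12)

    def test_kaczmarz_distance_to_solution_monotone(self, rng):
        """Per-step distance to the solution set never grows on consistent systems."""
        A = rng.uniform(0.0, 1.0, size=(6, 4))
        x_star = rng.uniform(0.0, 1.0, size=4)
        b = A @ x_star
        for lam in (0.5, 1.0, 1.5, 1.9):
            x = np.zeros(4)
            dist = np.linalg.norm(x - x_star)
            for _ in range(3):
                for i in range(6):
                    x = ba.art_step(x, A[i], b[i], lam=lam)
                    new_dist = np.linalg.norm(x - x_star)
                    assert new_dist <= dist + 1e-12
                    dist = new_dist


class TestPartition:
    @pytest.mark.parametrize(
        "m, M, sizes",
        [(10, 2, [5, 5]), (10, 3, [4, 3, 3]), (5, 5, [1, 1, 1, 1, 1]), (7, 4, [2, 2, 2, 1])],
    )
    def test_balanced_contiguous_blocks(self, m, M, sizes):
        part = ba.partition_rows(m, M)
        assert [hi - lo for lo, hi in part.blocks] == sizes
        assert part.blocks[0][0] == 0 and part.blocks[-1][1] == m
        for (_, hi), (lo, _) in zip(part.blocks, part.blocks[1:]):
            assert hi == lo

    @pytest.mark.parametrize("M", [0, 11])
    def test_invalid_block_count(self, M):
        with pytest.raises(ValueError):
            ba.partition_rows(10, M)

    @given(st.integers(1, 200), st.integers(1, 200))
    def test_cover_and_balance(self, m, M):
        if M > m:
            return
        part = ba.partition_rows(m, M)
        sizes = [hi - lo for lo, hi in part.blocks]
        assert sum(sizes) == m
        assert max(sizes) - min(sizes) <= 1


class TestBlockWeights:
    def test_single_block_is_identity_on_hit_columns(self, small_system):
        A, _, _, _ = small_system
        w = ba.block_weights(A, ba.partition_rows(A.m_rows, 1))
        hit = A.column_sums() > 0
        assert np.all(w.W[0, hit] == 1.0)

    def test_hand_computed_two_row_example(self):
        A = sp.csr_matrix(np.array([[1.0, 0.0], [3.0, 0.0]]))
        w = ba.block_weights(A, ba.partition_rows(2, 2))
        assert w.W[0, 0] == pytest.approx(0.25)
        assert w.W[1, 0] == pytest.approx(0.75)
        # untouched column: 1/M in every block
        assert w.W[0, 1] == w.W[1, 1] == pytest.approx(0.5)

    def test_weights_sum_to_one(self, small_system, rng):
        A, _, _, _ = small_system
        for M in (2, 3, 7):
            w = ba.block_weights(A, ba.partition_rows(A.m_rows, M))
            np.testing.assert_allclose(w.W.sum(axis=0), 1.0, atol=1e-12)
            assert np.all((w.W >= 0) & (w.W <= 1))


class TestPB:
    def test_single_block_iteration_matches_art_sweep_bitwise(self, small_system):
        A, b, truth, _ = small_system
        cfg = ba.SolverConfig(lam=1.4, max_iterations=1)
        part = ba.partition_rows(A.m_rows, 1)
        w = ba.block_weights(A, part)
        x_pb = ba.pb_iterate(np.zeros(A.n_cols), A, b, part, w, cfg)
        x_art = ba.art_solve(A, b, cfg, truth=truth).x
        assert np.array_equal(x_pb, x_art)

    def test_toy_system_matches_dense_reference(self):
        """pb_iterate agrees with an independent dense rendering of the scheme."""
        A = np.array([[1.0, 0.5], [0.2, 1.0], [0.7, 0.3], [0.4, 0.9]])
        b = np.array([1.0, 0.8, 0.9, 1.1])
        lam = 1.2
        x0 = np.array([0.1, 0.2])
        cfg = ba.SolverConfig(lam=lam, constraint="nonneg", constraint_timing="per_step")
        part = ba.partition_rows(4, 2)
        w = ba.block_weights(sp.csr_matrix(A), part)
        got = ba.pb_iterate(x0, sp.csr_matrix(A), b, part, w, cfg)

        # dense reference: per-block constrained ART sweeps, then weighted merge
        ys = []
        for lo, hi in ((0, 2), (2, 4)):
            y = x0.copy()
            for i in range(lo, hi):
                y = y + lam * (b[i] - A[i] @ y) / (A[i] @ A[i]) * A[i]
                y = np.maximum(y, 0.0)
            ys.append(y)
        col = A.sum(axis=0)
        expected = np.zeros(2)
        for k, (lo, hi) in enumerate(((0, 2), (2, 4))):
            expected += (A[lo:hi].sum(axis=0) / col) * ys[k]
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-14)

    def test_pb_solve_single_block_equals_art_bitwise(self, small_system):
        A, b, truth, _ = small_system
        cfg = ba.SolverConfig(lam=1.5, max_iterations=25)
        res_art = ba.art_solve(A, b, cfg, truth=truth)
        res_pb = ba.pb_solve(A, b, M=1, config=cfg, truth=truth)
        assert np.array_equal(res_art.x, res_pb.x)
        np.testing.assert_array_equal(
            res_art.history["delta"].to_numpy(), res_pb.history["delta"].to_numpy()
        )

    @pytest.mark.parametrize("workers", [2, 3])
    def test_worker_count_invariance(self, small_system, workers):
        """Thread count never changes the numbers (barrier + fixed merge order)."""
        A, b, truth, _ = small_system
        cfg = ba.SolverConfig(lam=1.5, max_iterations=15)
        ref = ba.pb_solve(A, b, M=3, config=cfg, truth=truth, workers=1)
        out = ba.pb_solve(A, b, M=3, config=cfg, truth=truth, workers=workers)
        assert np.array_equal(ref.x, out.x)
        np.testing.assert_array_equal(
            ref.history["delta"].to_numpy(), out.history["delta"].to_numpy()
        )

    def test_pb_converges_on_small_problem(self, small_system):
        A, b, truth, _ = small_system
        cfg = ba.SolverConfig(lam=1.5, max_iterations=2000, stop_delta=0.05)
        res = ba.pb_solve(A, b, M=3, config=cfg, truth=truth)
        assert res.min_delta() < 0.05
        assert res.partition is not None and res.partition.M == 3
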