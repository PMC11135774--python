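import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvxndl.learner import (
    CodingConfig,
    Dictionary,
    assign_nearest,
    column_objective,
    density,
    fit,
    fit_online_ndl,
    importance_scores,
    initialize,
    median_adjacent_distance,
    project_simplex,
    simplex_qp,
    solve_convex_weights,
    sparse_code,
    update_history,
    update_representatives,
)
from cvxndl.network_data import bin_fragments


def make_dictionary(reps_list, weights_list=None):
    if weights_list is None:
        weights_list = [np.full(r.shape[1], 1.0 / r.shape[1]) for r in reps_list]
    return Dictionary([np.asarray(r, float) for r in reps_list], weights_list)


class TestSimplexMachinery:
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=12),
    )
    @settings(max_examples=100, deadline=None)
    def test_projection_lands_on_simplex(self, v):
        w = project_simplex(np.array(v))
        assert abs(w.sum() - 1.0) < 1e-9
        assert np.all(w >= 0)

    def test_projection_of_simplex_point_is_identity(self):
        v = np.array([0.2, 0.5, 0.3])
        assert np.allclose(project_simplex(v), v)

    def test_qp_matches_grid_oracle(self, rng):
        # dense grid over the 3-simplex at resolution 0.01
        for trial in range(5):
            X = rng.random((6, 3))
            G = X.T @ X
            c = rng.normal(size=3)
            a = 1.0 + rng.random()
            w = simplex_qp(G, c, a)
            obj = a * w @ G @ w + 2 * c @ w
            best = np.inf
            for i in range(101):
                for j in range(101 - i):
                    wg = np.array([i, j, 100 - i - j]) / 100.0
                    best = min(best, a * wg @ G @ wg + 2 * c @ wg)
            assert obj <= best + 1e-5

    def test_qp_linear_case_picks_vertex(self):
        w = simplex_qp(np.zeros((3, 3)), np.array([0.3, -1.0, 0.5]), 0.0)
        assert np.array_equal(w, [0, 1, 0])


class TestSparseCode:
    def test_recovers_indicator_with_zero_penalty(self, rng):
        D = np.linalg.qr(rng.normal(size=(9, 3)))[0]  # near-orthogonal columns
        D = np.abs(D)
        code = sparse_code(D[:, 1], D, lam=0.0)
        assert np.allclose(D @ code, D[:, 1], atol=1e-8)

    def test_large_penalty_kills_code(self, rng):
        D = rng.random((9, 3))
        x = rng.random(9)
        lam = 2.1 * np.abs(D.T @ x).max()
        code = sparse_code(x, D, lam=lam)
        assert np.allclose(code, 0.0)

    def test_nonnegative(self, rng):
        D = rng.random((9, 4))
        x = rng.random(9)
        assert np.all(sparse_code(x, D, lam=0.5) >= 0)

    def test_matches_grid_search_oracle(self, rng):
        d, K = 6, 3
        D = rng.random((d, K))
        x = rng.random(d)
        lam = 0.3
        code = sparse_code(x, D, lam=lam)

        def objective(l):
            r = x - D @ l
            return r @ r + lam * np.abs(l).sum()

        # refine a coarse nonnegative grid around the reported optimum
        grid = np.linspace(0, 1.5, 16)
        best = min(
            objective(np.array(l)) for l in itertools.product(grid, repeat=K)
        )
        assert objective(code) <= best + 1e-6

    def test_nonfinite_input_rejected(self):
        D = np.ones((4, 2))
        with pytest.raises(ValueError, match="non-finite"):
            sparse_code(np.array([1.0, np.nan, 0, 0]), D, lam=0.1)


class TestAssignNearest:
    def test_exact_column_match(self, rng):
        D = rng.random((9, 5))
        assert assign_nearest(D[:, 3], D) == 3

    def test_tie_prefers_lower_index(self):
        D = np.array([[1.0, -1.0], [0.0, 0.0]])
        assert assign_nearest(np.zeros(2), D) == 0

    def test_matches_brute_force_scan(self, rng):
        D = rng.random((16, 6))
        for _ in range(100):
            x = rng.random(16)
            dists = [np.linalg.norm(x - D[:, j]) for j in range(6)]
            assert assign_nearest(x, D) == int(np.argmin(dists))


class TestUpdateHistory:
    def test_first_step_overwrites_prior(self, rng):
        A0 = rng.random((3, 3))
        B0 = rng.random((3, 4))
        code = rng.random(3)
        x = rng.random(4)
        A1, B1 = update_history(A0, B0, code, x, t=1)
        assert np.allclose(A1, np.outer(code, code))
        assert np.allclose(B1, np.outer(code, x))

    def test_zero_code_decays_history(self, rng):
        A0 = rng.random((3, 3))
        B0 = rng.random((3, 4))
        A1, B1 = update_history(A0, B0, np.zeros(3), np.zeros(4), t=5)
        assert np.allclose(A1, 0.8 * A0)
        assert np.allclose(B1, 0.8 * B0)

    def test_matches_direct_weighted_average(self, rng):
        K, d = 3, 5
        A = np.zeros((K, K))
        B = np.zeros((K, d))
        codes = rng.random((10, K))
        xs = rng.random((10, d))
        for t in range(1, 11):
            A, B = update_history(A, B, codes[t - 1], xs[t - 1], t)
        # with w_t = 1/t the history is the plain running mean
        assert np.allclose(A, np.mean([np.outer(c, c) for c in codes], axis=0))
        assert np.allclose(
            B, np.mean([np.outer(c, x) for c, x in zip(codes, xs)], axis=0)
        )

    def test_requires_positive_step(self):
        with pytest.raises(ValueError):
            update_history(np.zeros((2, 2)), np.zeros((2, 3)), np.ones(2), np.ones(3), 0)


class TestSolveConvexWeights:
    def test_single_representative(self, rng):
        dic = make_dictionary([rng.random((4, 1)), rng.random((4, 2))])
        w = solve_convex_weights(
            dic.reps[0], np.eye(2), rng.random((2, 4)), 0, dic.D
        )
        assert np.array_equal(w, [1.0])

    def test_vertex_optimum_when_target_is_a_rep(self, rng):
        # history demands exactly rep 1 of element 0; other column inactive
        reps = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        other = np.full((3, 1), 0.2)
        dic = make_dictionary([reps, other])
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        B = np.zeros((2, 3))
        B[0] = reps[:, 1]  # target = rep 1
        w = solve_convex_weights(reps, A, B, 0, dic.D)
        assert np.allclose(w, [0, 1, 0], atol=1e-5)

    def test_matches_simplex_grid_oracle(self, rng):
        d, m = 5, 3
        for _ in range(3):
            reps = rng.random((d, m))
            other = rng.random((d, 1))
            dic = make_dictionary([reps, other])
            A = rng.random((2, 2))
            A = A @ A.T + 0.1 * np.eye(2)
            B = rng.random((2, d))
            w = solve_convex_weights(reps, A, B, 0, dic.D)
            col = reps @ w
            dic._D[:, 0] = col
            obj = column_objective(dic, 0, col)
            best = np.inf
            for i in range(101):
                for j in range(101 - i):
                    wg = np.array([i, j, 100 - i - j]) / 100.0
                    cg = reps @ wg
                    best = min(best, column_objective(dic, 0, cg))
            assert obj <= best + 1e-5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            solve_convex_weights(
                np.zeros((3, 0)), np.eye(1), np.zeros((1, 3)), 0, np.zeros((3, 1))
            )


class TestInitialize:
    def test_reference_scale_partition(self, rng):
        pool = rng.random((500, 16))
        dic = initialize(pool, K=25, min_reps=10, rng=rng)
        sizes = dic.n_reps()
        assert len(sizes) == 25
        assert all(s >= 10 for s in sizes)
        assert sum(sizes) == 500
        dic.validate()

    def test_single_element_is_pool_mean(self, rng):
        pool = rng.random((30, 9))
        dic = initialize(pool, K=1, min_reps=5, rng=rng)
        assert np.allclose(dic.D[:, 0], pool.mean(axis=0))

    def test_identical_patches_give_identical_elements(self, rng):
        patch = (rng.random(9) > 0.5).astype(float)
        pool = np.tile(patch, (40, 1))
        dic = initialize(pool, K=4, min_reps=5, rng=rng)
        for j in range(4):
            assert np.allclose(dic.D[:, j], patch)

    def test_pool_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="K\\*min_reps"):
            initialize(rng.random((40, 9)), K=5, min_reps=10, rng=rng)

    def test_history_starts_empty(self, rng):
        dic = initialize(rng.random((40, 9)), K=2, min_reps=5, rng=rng)
        assert not dic.A_hist.any() and not dic.B_hist.any() and dic.t == 0


class TestUpdateRepresentatives:
    def _toy_dictionary(self, rng, m=3, d=4):
        reps = rng.random((d, m))
        other = rng.random((d, 1))
        dic = make_dictionary([reps, other])
        code = np.array([0.8, 0.1])
        x_hist = rng.random(d)
        dic.A_hist, dic.B_hist = update_history(
            dic.A_hist, dic.B_hist, code, x_hist, t=1
        )
        return dic

    def test_newcomer_rejected_when_worse(self, rng):
        # history optimum is the current centroid; a far-away newcomer is
        # removed again and the representative set survives unchanged
        reps = np.array(
            [[1.0, 0, 0, 0], [0, 1.0, 0, 0], [0, 0, 1.0, 0], [0, 0, 0, 1.0]]
        )[:, :3]
        dic = make_dictionary([reps])
        target = reps.mean(axis=1)
        code = np.array([1.0])
        dic.A_hist, dic.B_hist = update_history(
            dic.A_hist, dic.B_hist, code, target, t=1
        )
        # make stored weights history-optimal before the update
        w_opt = solve_convex_weights(reps, dic.A_hist, dic.B_hist, 0, dic.D)
        dic.set_element(0, reps, w_opt)
        before = dic.reps[0].copy()
        newcomer = np.full(4, 10.0)
        update_representatives(dic, 0, newcomer, n_max=3)
        assert np.array_equal(dic.reps[0], before)

    def test_single_rep_replacement_keeps_one(self, rng):
        dic = self._toy_dictionary(rng, m=1)
        x = rng.random(4)
        update_representatives(dic, 0, x, n_max=2)
        assert dic.reps[0].shape[1] == 2  # capacity allows both
        update_representatives(dic, 0, rng.random(4), n_max=2)
        assert dic.reps[0].shape[1] == 2  # one of the three was dropped

    def test_removal_matches_exhaustive_oracle(self, rng):
        for trial in range(5):
            dic = self._toy_dictionary(rng, m=3)
            x = rng.random(4)
            X_full = np.column_stack([dic.reps[0], x])
            # oracle: evaluate every removal candidate by brute force
            objs = []
            for i in range(4):
                keep = [j for j in range(4) if j != i]
                Xs = X_full[:, keep]
                w = solve_convex_weights(Xs, dic.A_hist, dic.B_hist, 0, dic.D)
                objs.append(column_objective(dic, 0, Xs @ w))
            # replicate the tie rule: newcomer wins ties
            best_i = int(np.argmin(objs))
            if objs[3] <= objs[best_i] + 1e-12:
                best_i = 3
            expected = X_full[:, [j for j in range(4) if j != best_i]]
            update_representatives(dic, 0, x, n_max=3)
            assert np.allclose(dic.reps[0], expected)

    def test_update_never_increases_column_objective(self, rng):
        dic = self._toy_dictionary(rng, m=3)
        for _ in range(10):
            # re-solve incumbent weights, then offer a new sample
            w_inc = solve_convex_weights(
                dic.reps[0], dic.A_hist, dic.B_hist, 0, dic.D, w0=dic.weights[0]
            )
            obj_before = column_objective(dic, 0, dic.reps[0] @ w_inc)
            update_representatives(dic, 0, rng.random(4), n_max=3)
            obj_after = column_objective(dic, 0, dic.D[:, 0])
            assert obj_after <= obj_before + 1e-9

    def test_capacity_respected_after_bulk_trim(self, rng):
        reps = rng.random((4, 12))  # oversized carryover set
        dic = make_dictionary([reps])
        code = np.array([1.0])
        dic.A_hist, dic.B_hist = update_history(
            dic.A_hist, dic.B_hist, code, rng.random(4), t=1
        )
        update_representatives(dic, 0, rng.random(4), n_max=5)
        assert dic.reps[0].shape[1] == 5
        dic.validate(n_max=5)


class TestFit:
    def test_constant_stream_fixed_point(self, rng):
        patch = (rng.random(9) > 0.4).astype(float)
        pool = np.tile(patch, (20, 1))
        dic = initialize(pool, K=1, min_reps=5, rng=rng)
        config = CodingConfig(lam=0.0, K=1, k=3, n_max=5, min_reps=5, window=5, tol=1e-6)
        stream = iter([patch.copy() for _ in range(50)])
        dic, state = fit(stream, dic, config)
        assert np.allclose(dic.D[:, 0], patch, atol=1e-8)
        assert state.converged

    def test_empty_stream_rejected(self, rng):
        dic = initialize(rng.random((10, 4)), K=1, min_reps=2, rng=rng)
        config = CodingConfig(lam=0.0, K=1, k=2, n_max=4, min_reps=2)
        with pytest.raises(ValueError, match="empty"):
            fit(iter([]), dic, config)

    def test_invariants_hold_after_training(self, rng):
        pool = (rng.random((120, 16)) > 0.6).astype(float)
        dic = initialize(pool[:60], K=3, min_reps=5, rng=rng)
        config = CodingConfig(lam=0.5, K=3, k=4, n_max=8, min_reps=5, window=20)
        dic, state = fit(iter(pool[60:]), dic, config)
        dic.validate(n_max=8)
        assert state.t == 60
        assert len(state.assignments) == 60

    def test_online_ndl_baseline_runs(self, rng):
        pool = (rng.random((80, 16)) > 0.6).astype(float)
        D0 = rng.random((16, 3))
        config = CodingConfig(lam=0.5, K=3, k=4, window=20)
        D, state = fit_online_ndl(iter(pool), D0, config)
        assert D.shape == (16, 3)
        assert D.min() >= 0 and D.max() <= 1
        assert state.t == 80


class TestSummaries:
    def test_importance_single_element(self):
        assert importance_scores(np.array([[2.0]])) == pytest.approx([1.0])

    def test_importance_equal_usage(self):
        gamma = importance_scores(np.diag([3.0, 3.0, 3.0, 3.0]))
        assert np.allclose(gamma, 0.25)

    def test_importance_forced_arithmetic(self):
        gamma = importance_scores(np.diag([1.0, 2.0]))
        assert np.allclose(gamma, [0.2, 0.8])

    def test_importance_sums_to_one(self, rng):
        A = rng.random((6, 6))
        A = A @ A.T
        assert importance_scores(A).sum() == pytest.approx(1.0)

    def test_importance_no_usage_error(self):
        with pytest.raises(ValueError, match="no usage"):
            importance_scores(np.zeros((3, 3)))

    @pytest.mark.parametrize(
        "element,k,expected",
        [
            (np.ones(9), 3, 1.0),
            (np.zeros(9), 3, 0.0),
            # 3-path patch: 4 ones among 9 entries
            (np.array([0, 1, 0, 1, 0, 1, 0, 1, 0], float), 3, 4 / 9),
        ],
    )
    def test_density(self, element, k, expected):
        assert density(element, k) == pytest.approx(expected)

    def test_median_adjacent_distance_contiguous(self):
        _, table = bin_fragments(
            [("chr1", i * 500, (i + 1) * 500) for i in range(4)]
        )
        tuples = np.array([[0, 1, 2], [1, 2, 3]])
        assert median_adjacent_distance(tuples, table) == 500.0

    def test_median_adjacent_distance_with_gap(self):
        _, table = bin_fragments(
            [("chr1", 0, 500), ("chr1", 500, 1000), ("chr1", 1000, 1500),
             ("chr1", 11000, 11500)]
        )
        # gaps 500, 500, 10000 -> median 500
        tuples = np.array([[0, 1, 2, 3]])
        assert median_adjacent_distance(tuples, table) == 500.0

    def test_median_matches_sort_oracle(self, rng):
        frags = [("chr1", i * 500, (i + 1) * 500) for i in range(30)]
        _, table = bin_fragments(frags)
        tuples = rng.integers(0, 30, size=(15, 4))
        dists = []
        for row in tuples:
            for a, b in zip(row[:-1], row[1:]):
                dists.append(abs(int(a) - int(b)) * 500.0)
        assert median_adjacent_distance(tuples, table) == float(np.median(dists))

    def test_median_requires_tuples(self):
        _, table = bin_fragments([("chr1", 0, 500)])
        with pytest.raises(ValueError):
            median_adjacent_distance(None, table)
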