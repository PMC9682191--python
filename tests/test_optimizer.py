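import numpy as np
import pytest

import agmfs
from agmfs import (
    Hyperparams,
    ThetaSubproblem,
    ValidationError,
    build_theta_subproblem,
    compute_N,
    hadamard_trace,
    objective,
    solve_theta_alm,
    update_W,
    update_b,
)
from agmfs.optim import (
    _init_state,
    _scaled_copy,
    build_graphs,
    fit,
    stationarity_residual_b,
    stationarity_residual_W,
)


from _oracles import (
    brute_force_simplex as _brute_force_simplex,
    projected_gradient as _projected_gradient,
    random_model_state as _random_state,
    smoothed_l21_least_squares as _smoothed_l21_least_squares,
)


def _naive_objective(state, data, graphs, hp):
    """Term-by-term re-evaluation from the definitions, with loops."""
    n = data.n
    segs = state.theta_segments()
    preds = []
    for X, W, seg in zip(data.blocks, state.W, segs):
        preds.append(W.T @ np.diag(seg) @ X.T)
    if hp.coupling == "additive":
        R = sum(preds) + np.outer(state.b, np.ones(n)) - data.Y
        loss = np.sum(R**2)
    else:
        loss = sum(
            np.sum((P + np.outer(state.b, np.ones(n)) - data.Y) ** 2)
            for P in preds
        )
    pen = 0.0
    for W in state.W:
        for i in range(W.shape[0]):
            pen += np.sqrt(W[i] @ W[i] + hp.epsilon)
    graph = 0.0
    if hp.beta:
        for X, W, g in zip(data.blocks, state.W, graphs):
            L = np.eye(n) - g.B @ g.B.T
            graph += np.trace(W.T @ X.T @ L @ X @ W)
    return loss + hp.alpha * pen + hp.beta * graph


class TestObjective:
    def test_zero_model_equals_label_norm(self, small_synthetic):
        data, _ = small_synthetic
        hp = Hyperparams(beta=0.0)
        state = _init_state(data)
        state.theta[:] = 0.0
        val = objective(state, data, [None] * len(data.blocks), hp)
        # W = 0, b = 0: only the label norm and the epsilon floor remain
        eps_floor = hp.alpha * np.sqrt(hp.epsilon) * data.total_dim
        assert abs(val - (np.sum(data.Y**2) + eps_floor)) < 1e-9

    @pytest.mark.parametrize("coupling", ["additive", "independent"])
    def test_matches_naive_recomputation(self, small_synthetic, rng, coupling):
        data, _ = small_synthetic
        hp = Hyperparams(alpha=0.3, beta=0.7, coupling=coupling, m_anchors=10, k_nn=3)
        graphs = build_graphs(data, hp)
        state = _random_state(data, rng)
        fast = objective(state, data, graphs, hp)
        slow = _naive_objective(state, data, graphs, hp)
        assert abs(fast - slow) < 1e-10 * max(1.0, abs(slow))

    def test_graph_term_vanishes_at_zero_weights(self, small_synthetic):
        data, _ = small_synthetic
        state = _init_state(data)
        hp0 = Hyperparams(beta=0.0)
        hp1 = Hyperparams(beta=1.0, m_anchors=10, k_nn=3)
        graphs = build_graphs(data, hp1)
        assert objective(state, data, graphs, hp0) == pytest.approx(
            objective(state, data, graphs, hp1)
        )


class TestUpdateB:
    def test_zero_weights_gives_label_row_means(self, small_synthetic):
        data, _ = small_synthetic
        state = _init_state(data)
        b = update_b(state, data, Hyperparams())
        np.testing.assert_allclose(b, data.Y.mean(axis=1), atol=1e-12)

    @pytest.mark.parametrize("coupling", ["additive", "independent"])
    def test_numeric_gradient_vanishes(self, small_synthetic, rng, coupling):
        data, _ = small_synthetic
        hp = Hyperparams(coupling=coupling, beta=0.0)
        state = _random_state(data, rng)
        state.b = update_b(state, data, hp)

        def loss(bvec):
            st2 = _random_state(data, np.random.default_rng(0))
            st2.W = state.W
            st2.theta = state.theta
            st2.b = bvec
            return objective(st2, data, [None] * len(data.blocks), hp)

        h = 1e-6
        for j in range(len(state.b)):
            e = np.zeros_like(state.b)
            e[j] = h
            g = (loss(state.b + e) - loss(state.b - e)) / (2 * h)
            assert abs(g) < 1e-6

    def test_closed_form_residual_zero(self, small_synthetic, rng):
        data, _ = small_synthetic
        hp = Hyperparams()
        state = _random_state(data, rng)
        state.b = update_b(state, data, hp)
        assert stationarity_residual_b(state, data, hp) < 1e-9


class TestUpdateW:
    def test_stationarity_after_solve(self, small_synthetic, rng):
        data, _ = small_synthetic
        hp = Hyperparams(alpha=0.2, beta=0.4, m_anchors=10, k_nn=3)
        graphs = build_graphs(data, hp)
        state = _random_state(data, rng)
        for v in range(len(data.blocks)):
            N_v = compute_N(state.W[v], hp.epsilon)
            state.W[v] = update_W(state, data, graphs, hp, v, N_v=N_v)
            res = stationarity_residual_W(state, data, graphs, hp, v, N_v=N_v)
            assert res < 1e-8

    def test_tiny_alpha_matches_least_squares(self, rng):
        """With alpha -> 0, beta = 0, the solve is ordinary least squares."""
        n, d, k = 30, 5, 2
        X = rng.normal(size=(n, d))
        y = rng.integers(0, 2, size=n)
        data = agmfs.MultiModalDataset(blocks=[X], Y=agmfs.one_hot(y, 2))
        hp = Hyperparams(alpha=1e-10, beta=0.0)
        state = _init_state(data)
        state.theta = np.full(d, 1.0 / d)
        state.b = np.zeros(k)
        W = update_W(state, data, [None], hp, 0, N_v=np.ones(d))
        Theta_X = X * state.theta[None, :]
        W_ols, *_ = np.linalg.lstsq(Theta_X, data.Y.T, rcond=None)
        fit_res = np.linalg.norm(Theta_X @ W - data.Y.T)
        ols_res = np.linalg.norm(Theta_X @ W_ols - data.Y.T)
        assert abs(fit_res - ols_res) < 1e-6

    def test_larger_alpha_shrinks(self, small_synthetic):
        data, _ = small_synthetic
        norms = []
        for alpha in (1.0, 1e6):
            hp = Hyperparams(alpha=alpha, beta=0.0)
            state = _init_state(data)
            W = update_W(state, data, [None] * 2, hp, 0, N_v=np.ones(data.dims[0]))
            norms.append(np.linalg.norm(W))
        assert norms[1] < norms[0]


class TestComputeN:
    def test_zero_row(self):
        N = compute_N(np.zeros((3, 2)), epsilon=1e-8)
        np.testing.assert_allclose(N, 5000.0)

    def test_unit_norm_row(self):
        W = np.array([[1.0, 0.0]])
        assert compute_N(W, 1e-16)[0] == pytest.approx(0.5, rel=1e-6)

    def test_scaling_monotonicity(self, rng):
        W = rng.normal(size=(6, 2))
        N1 = compute_N(W, 1e-8)
        N2 = compute_N(3.0 * W, 1e-8)
        assert (N2 < N1).all()


class TestHadamardTrace:
    def test_all_ones_is_trace_of_product(self, rng):
        B, C = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        assert hadamard_trace(np.ones(4), B, C) == pytest.approx(
            np.trace(B @ C), rel=1e-12
        )

    def test_zero_vector(self, rng):
        B, C = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        assert hadamard_trace(np.zeros(3), B, C) == 0.0

    def test_identity_against_dense_products(self, rng):
        for _ in range(100):
            a = rng.normal(size=5)
            B = rng.normal(size=(5, 5))
            C = rng.normal(size=(5, 5))
            A = np.diag(a)
            dense = np.trace(A @ B @ A @ C)
            assert abs(hadamard_trace(a, B, C) - dense) < 1e-10 * max(
                1.0, abs(dense)
            )

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            hadamard_trace(np.ones(3), np.eye(4), np.eye(4))


class TestThetaSubproblem:
    def test_zero_weights_give_zero_subproblem(self, small_synthetic):
        data, _ = small_synthetic
        state = _init_state(data)
        sub = build_theta_subproblem(state, data, Hyperparams())
        assert np.all(sub.Q == 0) and np.all(sub.s == 0)

    def test_reproduces_centered_trace_objective(self, small_synthetic, rng):
        """theta' Q theta - theta' s equals the dense centered-trace form."""
        data, _ = small_synthetic
        state = _random_state(data, rng)
        sub = build_theta_subproblem(state, data, Hyperparams())
        X = data.concatenated()
        W = np.vstack(state.W)
        n = data.n
        H = np.eye(n) - np.ones((n, n)) / n
        for _ in range(5):
            t = rng.uniform(0, 1, size=data.total_dim)
            t /= t.sum()
            T = np.diag(t)
            dense = np.trace(T @ X.T @ H @ X @ T @ W @ W.T) - np.trace(
                2 * T @ X.T @ H @ data.Y.T @ W.T
            )
            qp = t @ sub.Q @ t - t @ sub.s
            assert abs(dense - qp) < 1e-9 * max(1.0, abs(dense))

    def test_constant_columns_are_annihilated(self, rng):
        X = np.ones((10, 4))
        y = np.array([0, 1] * 5)
        data = agmfs.MultiModalDataset(blocks=[X], Y=agmfs.one_hot(y, 2))
        state = _random_state(data, rng)
        sub = build_theta_subproblem(state, data, Hyperparams())
        np.testing.assert_allclose(sub.Q, 0.0, atol=1e-12)




class TestSolveThetaALM:
    def test_symmetric_two_dim(self):
        sub = ThetaSubproblem(Q=np.eye(2), s=np.zeros(2))
        th = solve_theta_alm(sub, Hyperparams())
        np.testing.assert_allclose(th, [0.5, 0.5], atol=1e-6)

    def test_hand_kkt_vertex(self):
        sub = ThetaSubproblem(Q=np.eye(2), s=np.array([2.0, 0.0]))
        th = solve_theta_alm(sub, Hyperparams())
        np.testing.assert_allclose(th, [1.0, 0.0], atol=1e-6)

    def test_flat_objective_returns_feasible(self):
        sub = ThetaSubproblem(Q=np.zeros((4, 4)), s=np.zeros(4))
        th = solve_theta_alm(sub, Hyperparams())
        assert th.min() >= -1e-8
        assert abs(th.sum() - 1.0) < 1e-6

    def test_matches_brute_force_d3(self, rng):
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            Q = A @ A.T
            s = rng.normal(size=3)
            sub = ThetaSubproblem(Q=Q, s=s)
            th = solve_theta_alm(sub, Hyperparams())
            _, f_grid = _brute_force_simplex(Q, s)
            f_alm = th @ Q @ th - th @ s
            assert f_alm <= f_grid + 1e-4

    def test_matches_projected_gradient_d20(self, rng):
        for _ in range(3):
            A = rng.normal(size=(20, 20))
            Q = A @ A.T
            s = rng.normal(size=20)
            sub = ThetaSubproblem(Q=Q, s=s)
            th = solve_theta_alm(sub, Hyperparams())
            _, f_pg = _projected_gradient(Q, s)
            f_alm = th @ Q @ th - th @ s
            assert f_alm <= f_pg + 1e-6 * max(1.0, abs(f_pg))

    def test_simplex_feasibility(self, rng):
        A = rng.normal(size=(10, 10))
        sub = ThetaSubproblem(Q=A @ A.T, s=rng.normal(size=10))
        th = solve_theta_alm(sub, Hyperparams())
        assert abs(th.sum() - 1.0) <= 1e-6
        assert th.min() >= -1e-8


class TestFit:
    def test_degenerate_single_class_labels(self):
        X = np.random.default_rng(0).normal(size=(12, 4))
        Y = np.zeros((2, 12))
        Y[0] = 1.0  # all samples in class 0
        data = agmfs.MultiModalDataset(blocks=[X], Y=Y)
        hp = Hyperparams(beta=0.0, max_outer_iters=10)
        state = fit(data, hp)
        assert state.converged
        assert state.n_sweeps <= 3
        np.testing.assert_allclose(state.b, [1.0, 0.0], atol=1e-2)
        assert np.linalg.norm(np.vstack(state.W)) < 0.1

    def test_monotone_and_feasible_on_small_data(self, small_synthetic):
        data, _ = small_synthetic
        hp = Hyperparams(alpha=0.05, beta=0.5, m_anchors=12, k_nn=3, seed=0)
        state = fit(data, hp)
        h = state.objective_history
        assert all(b <= a * (1 + 1e-6) + 1e-12 for a, b in zip(h, h[1:]))
        assert abs(state.theta.sum() - 1.0) <= 1e-6
        assert state.theta.min() >= -1e-8

    @pytest.mark.parametrize("alpha,beta", [(1e-3, 1e-3), (1e3, 1e3)])
    def test_grid_extremes_terminate(self, small_synthetic, alpha, beta):
        data, _ = small_synthetic
        hp = Hyperparams(alpha=alpha, beta=beta, m_anchors=12, k_nn=3, seed=1)
        state = fit(data, hp)
        assert abs(state.theta.sum() - 1.0) <= 1e-6
        assert state.theta.min() >= -1e-8

    def test_independent_coupling_runs(self, small_synthetic):
        data, _ = small_synthetic
        hp = Hyperparams(coupling="independent", m_anchors=12, k_nn=3)
        state = fit(data, hp)
        assert state.objective_history
        assert abs(state.theta.sum() - 1.0) <= 1e-6



def test_frozen_theta_reduction_matches_l21_solver(small_synthetic):
    """With beta=0 and theta frozen uniform, the fit is a plain smoothed-l2,1
    least-squares problem on the concatenated, uniformly scaled features."""
    data, _ = small_synthetic
    hp = Hyperparams(
        alpha=0.5, beta=0.0, outer_tol=1e-12, max_outer_iters=500, seed=0
    )
    state = fit(data, hp, scale=True, freeze_theta=True)
    work, _, _ = _scaled_copy(data)
    X = work.concatenated() / data.total_dim  # uniform theta absorbed into X
    oracle = _smoothed_l21_least_squares(X, work.Y, hp.alpha, hp.epsilon)
    ours = state.objective_history[-1]
    assert abs(ours - oracle) <= 1e-6 * max(1.0, abs(oracle))
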