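"""Last-layer solvers: Lagrange-dual dictionary and feature-sign coding."""

import itertools

import numpy as np
import pytest

from grdsr.graph import build_graph
from grdsr.sparse import (
    SparseCodeProblem,
    _feature_sign_core,
    _fs_objective,
    dual_objective,
    feature_sign_step,
    sparse_layer_objective,
    update_codes_feature_sign,
    update_dictionary_dual,
)


def _enumerate_sign_patterns(Q, b, beta):
    """Brute-force optimum over all 3^k sign patterns (oracle)."""
    k = len(b)
    best = np.inf
    for signs in itertools.product((-1.0, 0.0, 1.0), repeat=k):
        s = np.array(signs)
        h = np.zeros(k)
        idx = np.flatnonzero(s)
        if idx.size:
            try:
                ha = np.linalg.solve(Q[np.ix_(idx, idx)], b[idx] - 0.5 * beta * s[idx])
            except np.linalg.LinAlgError:
                continue
            if not np.all(np.sign(ha) == s[idx]):
                continue
            h[idx] = ha
        best = min(best, _fs_objective(Q, b, beta, h))
    return best


def _projected_subgradient(Q, b, beta, n_iter=10_000):
    """Slow but independent subgradient-descent oracle."""
    k = len(b)
    h = np.zeros(k)
    best_h, best_f = h.copy(), _fs_objective(Q, b, beta, h)
    lip = 2 * np.linalg.eigvalsh(Q).max()
    for t in range(1, n_iter + 1):
        g = 2 * (Q @ h - b) + beta * np.sign(h)
        h = h - (1.0 / (lip * np.sqrt(t))) * g
        f = _fs_objective(Q, b, beta, h)
        if f < best_f:
            best_f, best_h = f, h.copy()
    return best_h, best_f


class TestDualDictionary:
    def test_inactive_constraints_return_least_squares(self, rng):
        H = rng.standard_normal((3, 20))
        W_true = rng.standard_normal((5, 3))
        W_true *= 0.4 / np.linalg.norm(W_true, axis=0)  # small atoms
        H_prev = W_true @ H
        W = update_dictionary_dual(H_prev, H)
        W_ls = H_prev @ H.T @ np.linalg.inv(H @ H.T)
        np.testing.assert_allclose(W, W_ls, atol=1e-8)

    def test_single_atom_matches_grid_search(self, rng):
        # 1-D dual: brute-force gamma over a dense grid
        H = rng.standard_normal((1, 30)) * 2.0
        H_prev = rng.standard_normal((4, 30)) * 3.0
        W, dual = update_dictionary_dual(H_prev, H, return_dual=True)
        grid = np.linspace(0.0, 1000.0, 200001)
        G = float((H @ H.T)[0, 0])
        P = H_prev @ H.T
        vals = float((P.T @ P)[0, 0]) / (G + grid) + grid
        g_star = grid[np.argmin(vals)]
        assert dual.gamma[0] == pytest.approx(g_star, abs=grid[1] - grid[0] + 1e-6)

    def test_kkt_at_optimum(self, rng):
        # feasibility, and complementary slackness: active multipliers
        # force unit atom norms
        for seed in range(15):
            r = np.random.default_rng(seed)
            H = r.standard_normal((4, 25))
            H_prev = r.standard_normal((6, 25)) * r.choice([0.5, 2.0, 5.0])
            W, dual = update_dictionary_dual(H_prev, H, return_dual=True)
            norms = np.linalg.norm(W, axis=0)
            assert norms.max() <= 1 + 1e-6
            active = dual.gamma > 1e-6
            np.testing.assert_allclose(norms[active], 1.0, atol=1e-5)

    def test_dual_no_worse_than_feasible_zero_projection(self, rng):
        H = rng.standard_normal((3, 15))
        H_prev = rng.standard_normal((5, 15)) * 4.0
        W = update_dictionary_dual(H_prev, H)
        W_proj = H_prev @ H.T @ np.linalg.inv(H @ H.T)
        W_proj /= np.maximum(np.linalg.norm(W_proj, axis=0), 1.0)
        assert np.linalg.norm(H_prev - W @ H) <= np.linalg.norm(H_prev - W_proj @ H) + 1e-9


class TestDualObjective:
    def test_orthonormal_rows_zero_gamma(self, rng):
        H = np.linalg.qr(rng.standard_normal((10, 3)))[0].T  # orthonormal rows
        H_prev = rng.standard_normal((4, 10))
        val = dual_objective(np.zeros(3), H_prev, H)
        assert val == pytest.approx(np.linalg.norm(H_prev @ H.T) ** 2)

    def test_trace_term_shift(self, rng):
        H = rng.standard_normal((3, 12))
        H_prev = rng.standard_normal((5, 12))
        g0 = np.array([1.0, 2.0, 0.5])
        # the Tr(A) part adds c per atom; the inverse part shrinks, so the
        # difference is bounded by c*k from above
        c = 0.7
        assert dual_objective(g0 + c, H_prev, H) <= dual_objective(g0, H_prev, H) + c * 3

    def test_gradient_matches_finite_differences(self, rng):
        H = rng.standard_normal((3, 20))
        H_prev = rng.standard_normal((5, 20))
        gamma = np.array([0.5, 1.5, 0.2])
        G = H @ H.T
        P = H_prev @ H.T
        W = P @ np.linalg.inv(G + np.diag(gamma))
        analytic = 1.0 - np.sum(W * W, axis=0)
        eps = 1e-6
        for i in range(3):
            e = np.zeros(3)
            e[i] = eps
            fd = (
                dual_objective(gamma + e, H_prev, H)
                - dual_objective(gamma - e, H_prev, H)
            ) / (2 * eps)
            assert fd == pytest.approx(analytic[i], abs=1e-5)

    def test_negative_gamma_rejected(self, rng):
        with pytest.raises(ValueError):
            dual_objective(np.array([-0.1]), np.ones((2, 4)), np.ones((1, 4)))


class TestFeatureSign:
    def test_scalar_soft_threshold(self):
        # W = [1], alpha = 0: argmin (x - h)^2 + beta|h| soft-thresholds x
        for x in (-2.0, -0.3, 0.0, 0.4, 3.0):
            for beta in (0.0, 0.5, 1.2):
                prob = SparseCodeProblem(
                    target=np.array([x]),
                    W=np.array([[1.0]]),
                    coupling=np.zeros(1),
                    L_ii=0.0,
                    alpha=0.0,
                    beta=beta,
                )
                h = feature_sign_step(prob)
                expected = np.sign(x) * max(abs(x) - beta / 2.0, 0.0)
                assert h[0] == pytest.approx(expected, abs=1e-10)

    def test_zero_vector_when_beta_dominates(self, rng):
        W = rng.standard_normal((4, 3))
        y = rng.standard_normal(4)
        u = rng.standard_normal(3) * 0.1
        alpha = 0.2
        activation = np.abs(2 * W.T @ y - 2 * alpha * u).max()
        prob = SparseCodeProblem(
            target=y, W=W, coupling=u, L_ii=0.5, alpha=alpha, beta=activation * 1.01
        )
        h = feature_sign_step(prob)
        assert not h.any()

    def test_orthogonal_dictionary_decouples(self, rng):
        W = np.linalg.qr(rng.standard_normal((5, 2)))[0]
        y = rng.standard_normal(5)
        beta = 0.4
        prob = SparseCodeProblem(
            target=y, W=W, coupling=np.zeros(2), L_ii=0.0, alpha=0.0, beta=beta
        )
        h = feature_sign_step(prob)
        proj = W.T @ y
        expected = np.sign(proj) * np.maximum(np.abs(proj) - beta / 2.0, 0.0)
        np.testing.assert_allclose(h, expected, atol=1e-9)

    def test_matches_sign_pattern_enumeration(self):
        for seed in range(40):
            r = np.random.default_rng(seed)
            k = int(r.integers(2, 6))
            A = r.standard_normal((k + 2, k))
            Q = A.T @ A + 1e-8 * np.eye(k)
            b = r.standard_normal(k) * r.choice([0.3, 1.0, 4.0])
            beta = float(r.choice([0.01, 0.3, 1.0, 5.0]))
            h = _feature_sign_core(Q, b, beta, np.zeros(k))
            best = _enumerate_sign_patterns(Q, b, beta)
            assert _fs_objective(Q, b, beta, h) <= best + 1e-8 * max(1, abs(best))

    def test_no_worse_than_subgradient_oracle(self):
        for seed in range(3):
            r = np.random.default_rng(100 + seed)
            A = r.standard_normal((7, 5))
            Q = A.T @ A + 0.1 * np.eye(5)
            b = r.standard_normal(5) * 2
            beta = 0.8
            h = _feature_sign_core(Q, b, beta, np.zeros(5))
            _, f_oracle = _projected_subgradient(Q, b, beta)
            assert _fs_objective(Q, b, beta, h) <= f_oracle + 1e-6

    def test_immediate_return_when_start_optimal(self):
        Q = np.eye(2)
        b = np.array([0.1, -0.05])  # |grad(0)| = 2|b| < beta
        h = _feature_sign_core(Q, b, 1.0, np.zeros(2))
        assert not h.any()


class TestCodeSweep:
    def test_unregularized_sweep_is_least_squares(self, rng):
        W = rng.standard_normal((6, 3))
        H_prev = rng.standard_normal((6, 10))
        L = np.zeros((10, 10))
        H = update_codes_feature_sign(H_prev, W, L, alpha=0.0, beta=0.0)
        expected = np.linalg.solve(W.T @ W, W.T @ H_prev)
        np.testing.assert_allclose(H, expected, atol=1e-7)

    def test_subgradient_optimality_per_column(self, rng):
        X = rng.standard_normal((5, 15))
        g = build_graph(X, k=3)
        W = rng.standard_normal((5, 3))
        alpha, beta = 0.2, 0.5
        H = update_codes_feature_sign(X, W, g.L, alpha, beta)
        # run to stability then check the stated subgradient conditions
        for _ in range(20):
            H = update_codes_feature_sign(X, W, g.L, alpha, beta, H_init=H)
        grad = 2 * (W.T @ W @ H - W.T @ X + alpha * H @ g.L)
        nz = H != 0
        assert np.all(np.abs(grad[nz] + beta * np.sign(H[nz])) <= 1e-5)
        assert np.all(np.abs(grad[~nz]) <= beta + 1e-5)

    def test_objective_never_increases(self, rng):
        X = rng.standard_normal((4, 12))
        g = build_graph(X, k=3)
        W = rng.standard_normal((4, 3))
        alpha, beta = 0.3, 0.4
        H = np.zeros((3, 12))
        prev = sparse_layer_objective(X, W, H, g.L, alpha, beta)
        for _ in range(5):
            H = update_codes_feature_sign(X, W, g.L, alpha, beta, H_init=H)
            cur = sparse_layer_objective(X, W, H, g.L, alpha, beta)
            assert cur <= prev * (1 + 1e-9) + 1e-12
            prev = cur

    def test_block_sweep_descends_layer_objective(self):
        # one dictionary-then-codes sweep never increases the last-layer
        # objective, across seeds
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((5, 14))
            g = build_graph(X, k=3)
            alpha, beta = 0.1, 0.3
            W = r.standard_normal((5, 3))
            W /= np.linalg.norm(W, axis=0)
            H = update_codes_feature_sign(X, W, g.L, alpha, beta)
            before = sparse_layer_objective(X, W, H, g.L, alpha, beta)
            W = update_dictionary_dual(X, H)
            H = update_codes_feature_sign(X, W, g.L, alpha, beta, H_init=H)
            after = sparse_layer_objective(X, W, H, g.L, alpha, beta)
            assert after <= before * (1 + 1e-9) + 1e-12

    def test_sparsity_nonincreasing_in_beta(self):
        # aggregate nonzero count over fixed instances; tiny slack because
        # the lasso path allows isolated local increases
        betas = [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]
        total = []
        instances = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((5, 12))
            g = build_graph(X, k=3)
            W = r.standard_normal((5, 4))
            W /= np.linalg.norm(W, axis=0)
            instances.append((X, g, W))
        for beta in betas:
            nnz = 0
            for X, g, W in instances:
                H = update_codes_feature_sign(X, W, g.L, 0.1, beta)
                nnz += np.count_nonzero(H)
            total.append(nnz)
        for a, b in zip(total, total[1:]):
            assert b <= a + 1
        assert total[-1] == 0  # beta = 1000 kills every coefficient
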