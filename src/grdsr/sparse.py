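"""Last-layer updates: dual dictionary learning and feature-sign sparse coding.

The last layer of the deep factorization solves

    min_{W, H}  ||H_prev - W H||_F^2 + alpha * Tr(H L H^T) + beta * sum_i ||h_i||_1
    s.t.        ||w_j||^2 <= 1  for every atom w_j,

alternating two convex subproblems:

* **Dictionary** (H fixed): the norm constraints are handled through their
  Lagrange dual.  With ``A = diag(gamma)`` the dual is the smooth convex
  problem ``min_{gamma >= 0} Tr(P (G + A)^+ P^T) + Tr(A)`` where
  ``G = H H^T`` and ``P = H_prev H^T``; the primal is recovered in closed
  form as ``W = P (G + A*)^+``.  We minimize the dual by projected Newton
  with backtracking.  A convenient identity: the dual gradient is
  ``1 - ||w_j||^2`` at the current recovered dictionary, so the KKT
  conditions read off directly.

* **Codes** (W fixed): the objective is jointly convex in H and separable
  per sample up to the graph coupling, so columns are updated cyclically.
  Expanding ``Tr(H L H^T)`` around column i gives the per-column problem

      min_h ||y - W h||^2 + alpha*L_ii*h^T h + 2*alpha*h^T u + beta*||h||_1,

  with ``u = sum_{j != i} L_ij h_j``, an L1-regularized positive-definite
  quadratic solved exactly by feature-sign search: guess the sign pattern
  of the solution, solve the reduced unconstrained quadratic analytically,
  and line-search across sign flips until the subgradient conditions hold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import optimize

from .exceptions import ConvergenceError, NumericalError

__all__ = [
    "DualVariables",
    "SparseCodeProblem",
    "dual_objective",
    "update_dictionary_dual",
    "feature_sign_step",
    "update_codes_feature_sign",
    "sparse_layer_objective",
]

logger = logging.getLogger(__name__)

_PINV_RCOND = 1e-12


@dataclass
class DualVariables:
    """Nonnegative multipliers gamma for the atom-norm constraints."""

    gamma: np.ndarray

    @property
    def A(self) -> np.ndarray:
        return np.diag(self.gamma)


@dataclass
class SparseCodeProblem:
    """One column's L1 sparse-coding problem with graph coupling.

    ``target`` is the column of the previous layer's codes being encoded,
    ``coupling`` the vector ``sum_{j != i} L_ij h_j`` of current neighbour
    codes, ``L_ii`` the sample's own Laplacian diagonal.
    """

    target: np.ndarray
    W: np.ndarray
    coupling: np.ndarray
    L_ii: float
    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")

    def quadratic(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (Q, b) with smooth part ``h^T Q h - 2 b^T h + const``."""
        k = self.W.shape[1]
        Q = self.W.T @ self.W + self.alpha * self.L_ii * np.eye(k)
        b = self.W.T @ self.target - self.alpha * np.asarray(self.coupling)
        return Q, b


# ---------------------------------------------------------------------------
# dictionary update via the Lagrange dual
# ---------------------------------------------------------------------------


def _dual_terms(gamma, G, P):
    """Return (value, W) of the dual at gamma; W is the recovered primal."""
    M = G + np.diag(gamma)
    try:
        Minv = np.linalg.inv(M)
        # reject badly conditioned "successes"
        if not np.all(np.isfinite(Minv)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("Gram + A numerically singular; using pseudoinverse", stacklevel=3)
        Minv = np.linalg.pinv(M, rcond=_PINV_RCOND)
    W = P @ Minv
    value = float(np.sum(W * P)) + float(gamma.sum())
    return value, W, Minv


def dual_objective(gamma: np.ndarray, H_prev: np.ndarray, H: np.ndarray) -> float:
    """Dual value ``Tr(P (G + diag(gamma))^+ P^T) + sum(gamma)``.

    ``G = H H^T``, ``P = H_prev H^T``.  Convex in gamma on ``gamma >= 0``.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("dual variables must be nonnegative")
    G = H @ H.T
    P = H_prev @ H.T
    value, _, _ = _dual_terms(gamma, G, P)
    return value


def _kkt_residual(gamma, W):
    grad = 1.0 - np.sum(W * W, axis=0)
    kkt = np.where(gamma > 1e-12, np.abs(grad), np.abs(np.minimum(grad, 0.0)))
    return float(kkt.max()) if kkt.size else 0.0


def _polish_if_needed(gamma, W, G, P, tol):
    """Bound-constrained quasi-Newton polish for a stalled dual iterate."""
    residual = _kkt_residual(gamma, W)
    if residual < tol:
        return gamma, W, residual

    def value_and_grad(g):
        val, W_g, _ = _dual_terms(g, G, P)
        return val, 1.0 - np.sum(W_g * W_g, axis=0)

    res = optimize.minimize(
        value_and_grad,
        gamma,
        jac=True,
        bounds=[(0.0, None)] * gamma.size,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-16, "gtol": 1e-12},
    )
    _, W_new, _ = _dual_terms(res.x, G, P)
    new_residual = _kkt_residual(res.x, W_new)
    if new_residual < residual:
        return res.x, W_new, new_residual
    return gamma, W, residual


def update_dictionary_dual(
    H_prev: np.ndarray,
    H: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    return_dual: bool = False,
):
    """Constrained dictionary ``argmin ||H_prev - W H||_F^2 s.t. ||w_j|| <= 1``.

    Solves the Lagrange dual in the multipliers gamma by projected Newton
    with Armijo backtracking, then recovers ``W = P (G + diag(gamma))^+``.
    If the unconstrained least-squares dictionary is already feasible it is
    returned directly (gamma = 0).

    Returns ``W`` or ``(W, DualVariables)`` when ``return_dual``.
    """
    H_prev = np.asarray(H_prev, dtype=float)
    H = np.asarray(H, dtype=float)
    k = H.shape[0]
    G = H @ H.T
    P = H_prev @ H.T

    gamma = np.zeros(k)
    value, W, Minv = _dual_terms(gamma, G, P)
    grad = 1.0 - np.sum(W * W, axis=0)  # dual gradient = 1 - ||w_j||^2
    if np.all(grad >= -tol):
        # all atom norms <= 1 at gamma = 0: constraints inactive
        if not np.all(np.isfinite(W)):
            raise NumericalError("dictionary update produced non-finite entries")
        return (W, DualVariables(gamma)) if return_dual else W

    # interior start keeps G + diag(gamma) well conditioned
    scale = max(float(np.trace(G)) / k, 1e-12)
    gamma = np.full(k, 1e-3 * scale)
    value, W, Minv = _dual_terms(gamma, G, P)

    for it in range(max_iter):
        grad = 1.0 - np.sum(W * W, axis=0)
        kkt = np.where(gamma > 1e-12, np.abs(grad), np.abs(np.minimum(grad, 0.0)))
        residual = float(kkt.max()) if k else 0.0
        if residual < tol:
            break

        # Hessian of the dual: 2 * (W^T W) .* Minv  (Schur product, PSD)
        Hess = 2.0 * (W.T @ W) * Minv
        damping = 1e-10 * max(np.trace(Hess) / k, 1.0)
        free = ~((gamma <= 1e-12) & (grad > 0))
        step = np.zeros(k)
        if np.any(free):
            Hf = Hess[np.ix_(free, free)] + damping * np.eye(int(free.sum()))
            try:
                step[free] = np.linalg.solve(Hf, -grad[free])
            except np.linalg.LinAlgError:
                step[free] = -grad[free]
        # descent safeguard: fall back to (projected) gradient direction
        if np.dot(step, grad) > 0:
            step = np.where(free, -grad, 0.0)

        if residual < 1e-3:
            # local phase: the Armijo decrease is below float noise of the
            # dual value, so take undamped Newton steps tracked by the KKT
            # residual (quadratic local convergence)
            cand = np.maximum(gamma + step, 0.0)
            cand_value, cand_W, cand_Minv = _dual_terms(cand, G, P)
            if _kkt_residual(cand, cand_W) < residual:
                gamma, value, W, Minv = cand, cand_value, cand_W, cand_Minv
                continue
            break  # no progress; polish below decides

        t = 1.0
        accepted = False
        for _ in range(60):
            cand = np.maximum(gamma + t * step, 0.0)
            cand_value, cand_W, cand_Minv = _dual_terms(cand, G, P)
            if cand_value <= value + 1e-4 * np.dot(grad, cand - gamma):
                gamma, value, W, Minv = cand, cand_value, cand_W, cand_Minv
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break  # Newton stalled; polish below decides
    gamma, W, residual = _polish_if_needed(gamma, W, G, P, tol)
    if residual >= 1e-6:
        raise ConvergenceError(
            f"dual dictionary solver did not converge "
            f"(KKT residual {residual:.3e})",
            last_iterate=gamma,
            residual=residual,
        )

    if not np.all(np.isfinite(W)):
        raise NumericalError("dictionary update produced non-finite entries")
    logger.debug("dual dictionary: max atom norm %.6f", np.linalg.norm(W, axis=0).max())
    return (W, DualVariables(gamma)) if return_dual else W


# ---------------------------------------------------------------------------
# feature-sign search
# ---------------------------------------------------------------------------


def _fs_objective(Q, b, beta, h):
    return float(h @ Q @ h - 2.0 * b @ h + beta * np.abs(h).sum())


def _ista_fallback(Q, b, beta, h0, n_iter=20000):
    """Deterministic proximal-gradient fallback for a cycling active set."""
    lip = 2.0 * float(np.linalg.eigvalsh(Q).max())
    if lip <= 0:
        return np.zeros_like(h0)
    t = 1.0 / lip
    h = h0.copy()
    for _ in range(n_iter):
        g = 2.0 * (Q @ h - b)
        z = h - t * g
        h = np.sign(z) * np.maximum(np.abs(z) - t * beta, 0.0)
    return h


@njit(cache=True)
def _fs_search_nb(Q, b, beta, h0, tol, max_steps):  # pragma: no cover - jitted
    """Numba kernel for feature-sign search; returns (h, ok_flag)."""
    k = Q.shape[0]
    h = h0.copy()
    theta = np.sign(h)
    active = h != 0.0
    best = h @ Q @ h - 2.0 * (b @ h) + beta * np.abs(h).sum()

    for _step in range(max_steps):
        grad = 2.0 * (Q @ h - b)
        support_ok = True
        for j in range(k):
            if active[j] and abs(grad[j] + beta * theta[j]) > tol:
                support_ok = False
                break
        if support_ok:
            jmax = -1
            vmax = 0.0
            for j in range(k):
                if not active[j] and abs(grad[j]) > vmax:
                    vmax = abs(grad[j])
                    jmax = j
            if jmax < 0 or vmax <= beta + tol:
                return h, True
            theta[jmax] = -1.0 if grad[jmax] > 0 else 1.0
            active[jmax] = True

        na = 0
        for j in range(k):
            if active[j]:
                na += 1
        idx = np.empty(na, np.int64)
        c = 0
        for j in range(k):
            if active[j]:
                idx[c] = j
                c += 1
        Qaa = np.empty((na, na))
        rhs = np.empty(na)
        h_old = np.empty(na)
        for p in range(na):
            for q in range(na):
                Qaa[p, q] = Q[idx[p], idx[q]]
            rhs[p] = b[idx[p]] - 0.5 * beta * theta[idx[p]]
            h_old[p] = h[idx[p]]
        h_new = np.linalg.solve(Qaa, rhs)

        # best point on the segment h_old -> h_new among the endpoint and
        # every zero crossing
        best_obj = 1e300
        best_pt = h_new
        for cand_j in range(-1, na):
            if cand_j < 0:
                pt = h_new
            else:
                ho = h_old[cand_j]
                hn = h_new[cand_j]
                if ho == 0.0 or (ho > 0) == (hn > 0) or ho == hn:
                    continue
                t = ho / (ho - hn)
                if not (0.0 < t < 1.0):
                    continue
                pt = h_old + t * (h_new - h_old)
                pt[cand_j] = 0.0
            val = pt @ Qaa @ pt
            lin = 0.0
            l1 = 0.0
            for p in range(na):
                lin += b[idx[p]] * pt[p]
                l1 += abs(pt[p])
            val = val - 2.0 * lin + beta * l1
            if val < best_obj:
                best_obj = val
                best_pt = pt.copy()

        for j in range(k):
            h[j] = 0.0
        for p in range(na):
            v = best_pt[p]
            if abs(v) < 1e-14:
                v = 0.0
            h[idx[p]] = v
        if best_obj > best + 1e-10 * max(1.0, abs(best)):
            return h, False  # cycling / numerical stall
        if best_obj < best:
            best = best_obj
        for j in range(k):
            active[j] = h[j] != 0.0
            theta[j] = np.sign(h[j])
    return h, False


def _feature_sign_core(Q, b, beta, h_init, tol=1e-9, max_steps=500):
    """Minimize ``h^T Q h - 2 b^T h + beta*||h||_1`` exactly (Q PD).

    Active-set sign search: maintain a sign vector theta on the active set,
    solve the reduced quadratic ``Q_aa h_a = b_a - (beta/2) theta_a``
    analytically, and take the best point on the segment to it, discarding
    coordinates that cross zero, until the subgradient optimality conditions
    hold: ``grad_j + beta*sign(h_j) = 0`` on the support and
    ``|grad_j| <= beta`` off it (grad of the smooth part).
    """
    Q = np.ascontiguousarray(Q, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    h0 = np.ascontiguousarray(h_init, dtype=np.float64)
    h, ok = _fs_search_nb(Q, b, float(beta), h0, float(tol), int(max_steps))
    if ok:
        return h

    warnings.warn(
        "feature-sign search cycled; falling back to proximal gradient",
        stacklevel=3,
    )
    h_fb = _ista_fallback(Q, b, beta, h)
    if _fs_objective(Q, b, beta, h_fb) <= _fs_objective(Q, b, beta, h):
        return h_fb
    return h


def feature_sign_step(problem: SparseCodeProblem, h_init: np.ndarray | None = None):
    """Exact minimizer of one column's graph-coupled L1 problem."""
    Q, b = problem.quadratic()
    k = Q.shape[0]
    if h_init is None:
        h_init = np.zeros(k)
    # PD safeguard: a rank-deficient dictionary with L_ii = 0 leaves Q PSD
    # only; an infinitesimal ridge keeps reduced solves well posed
    eigmin = float(np.linalg.eigvalsh(Q).min())
    if eigmin < 1e-12:
        Q = Q + (1e-12 - min(eigmin, 0.0) + 1e-12) * np.eye(k)
    return _feature_sign_core(Q, b, problem.beta, np.asarray(h_init, dtype=float))


def sparse_layer_objective(H_prev, W, H, L, alpha, beta) -> float:
    """Full last-layer objective (reconstruction + graph + L1)."""
    rec = float(np.linalg.norm(H_prev - W @ H, "fro") ** 2)
    smooth = float(np.sum((H @ L) * H))
    return rec + alpha * smooth + beta * float(np.abs(H).sum())


def update_codes_feature_sign(
    H_prev: np.ndarray,
    W: np.ndarray,
    L: np.ndarray,
    alpha: float,
    beta: float,
    H_init: np.ndarray | None = None,
) -> np.ndarray:
    """One cyclic sweep of exact per-column feature-sign updates.

    Columns are visited in ascending sample order; each column is minimized
    exactly with all others held at their current values, so the full
    (jointly convex) last-layer objective never increases.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    H_prev = np.asarray(H_prev, dtype=float)
    W = np.asarray(W, dtype=float)
    L = np.asarray(L, dtype=float)
    k, n = W.shape[1], H_prev.shape[1]
    H = np.zeros((k, n)) if H_init is None else np.asarray(H_init, dtype=float).copy()
    if H.shape != (k, n):
        raise ValueError(f"H_init must be {k}x{n}; got {H.shape}")

    WtW = W.T @ W
    WtY = W.T @ H_prev
    eye = np.eye(k)
    # Q_i = WtW + alpha*L_ii*I, so one eigenvalue bound covers all columns
    # (Laplacian diagonals are nonnegative)
    eigmin_base = float(np.linalg.eigvalsh(WtW).min())

    # KKT screening: columns already optimal given the current H are
    # skipped, so converged regions cost two GEMMs rather than an
    # active-set solve per column
    grad = 2.0 * (WtW @ H - WtY + alpha * (H @ L))
    nz = H != 0.0
    viol = np.any(
        np.where(nz, np.abs(grad + beta * np.sign(H)), np.abs(grad) - beta) > 1e-6,
        axis=0,
    )
    for i in np.flatnonzero(viol):
        coupling = H @ L[:, i] - L[i, i] * H[:, i]
        Q = WtW + alpha * L[i, i] * eye
        b = WtY[:, i] - alpha * coupling
        eigmin = eigmin_base + alpha * L[i, i]
        if eigmin < 1e-12:
            Q = Q + (1e-12 - min(eigmin, 0.0) + 1e-12) * eye
        try:
            H[:, i] = _feature_sign_core(Q, b, beta, H[:, i])
        except Exception as exc:  # pragma: no cover - defensive
            raise ConvergenceError(
                f"feature-sign failed on column {i}: {exc}"
            ) from exc
    if not np.all(np.isfinite(H)):
        raise NumericalError("sparse code update produced non-finite entries")
    logger.info(
        "feature-sign sweep: %.1f%% nonzeros", 100.0 * np.count_nonzero(H) / H.size
    )
    return H
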