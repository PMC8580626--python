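"""Closed-form updates for the intermediate (non-sparse) layers.

An intermediate layer ``i < l`` of the deep factorization solves

    min_{W_i, H_i}  ||X - Lambda_{i-1} W_i H_i||_F^2 + alpha * Tr(H_i L H_i^T)

where ``Lambda_{i-1} = W_1 ... W_{i-1}`` is the prefix product of the
earlier bases.  Setting the gradient to zero gives a pseudoinverse formula
for the basis and a Sylvester equation

    (W^T Lambda^T Lambda W) H + H (alpha L) = W^T Lambda^T X

for the codes.  Because both coefficient matrices are symmetric PSD here,
the Sylvester system is solved by simultaneous diagonalization; the
eigendecomposition of the (shared, fixed) Laplacian can be precomputed once
per fit and reused for every layer and sweep.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .exceptions import NumericalError

__all__ = [
    "update_basis_intermediate",
    "update_basis_intermediate_constrained",
    "solve_sylvester",
    "update_codes_intermediate",
]

logger = logging.getLogger(__name__)

# singular values below PINV_RCOND * sigma_max are treated as zero
PINV_RCOND = 1e-12


def update_basis_intermediate(
    X: np.ndarray, prefix: np.ndarray, H: np.ndarray
) -> np.ndarray:
    """Stationary basis ``W = (P^T P)^+ P^T X H^T (H H^T)^+`` with P the prefix.

    This is the least-squares minimizer of ``||X - P W H||_F^2`` in W; when
    both Gram matrices are invertible the gradient vanishes exactly at the
    result.
    """
    X = np.asarray(X, dtype=float)
    prefix = np.asarray(prefix, dtype=float)
    H = np.asarray(H, dtype=float)
    G_p = prefix.T @ prefix
    G_h = H @ H.T
    W = np.linalg.pinv(G_p, rcond=PINV_RCOND) @ (prefix.T @ X @ H.T) @ np.linalg.pinv(
        G_h, rcond=PINV_RCOND
    )
    if not np.all(np.isfinite(W)):
        raise NumericalError("basis update produced non-finite entries")
    return W


def _ball_constrained_column(sigma, U, b, q, w_current):
    """Minimize ``q*w'Gw - 2 w'b`` s.t. ``||w|| <= 1`` with ``G = U diag(sigma) U'``.

    Exact solution: the unconstrained stationary point if feasible,
    otherwise the boundary point ``((qG + gamma*I)^-1 b`` with the
    multiplier gamma solving the secular equation ``||w(gamma)|| = 1``
    (monotone in gamma; bisection with a Newton-tightened bracket).
    """
    if q <= 0:  # dead atom: objective does not depend on this column
        return w_current
    bt = U.T @ b
    denom0 = q * sigma
    if denom0.min() > 1e-14 * max(denom0.max(), 1.0):
        w = U @ (bt / denom0)
        if w @ w <= 1.0:
            return w

    # boundary case: Newton on the secular function 1/||w(gamma)|| - 1,
    # which is close to linear in gamma (standard trust-region trick);
    # converges from the right in a handful of iterations
    bt2 = bt * bt
    gamma = max(float(np.linalg.norm(bt)), 1e-30)  # ||w|| <= 1 here
    for _ in range(50):
        d = denom0 + gamma
        n2 = float(np.sum(bt2 / (d * d)))
        if n2 <= 0:
            break
        dn2 = -2.0 * float(np.sum(bt2 / (d * d * d)))
        g = n2**-0.5 - 1.0
        if abs(g) < 1e-13:
            break
        dg = -0.5 * n2**-1.5 * dn2
        step = g / dg
        new_gamma = gamma - step
        if new_gamma <= 0:
            new_gamma = 0.5 * gamma
        if abs(new_gamma - gamma) <= 1e-15 * max(gamma, 1.0):
            gamma = new_gamma
            break
        gamma = new_gamma
    return U @ (bt / (denom0 + gamma))


def update_basis_intermediate_constrained(
    X: np.ndarray,
    prefix: np.ndarray,
    H: np.ndarray,
    W_init: np.ndarray,
    max_cycles: int = 100,
    tol: float = 1e-12,
) -> np.ndarray:
    """Basis update with unit-norm column constraints ``||w_j|| <= 1``.

    Minimizes ``||X - P W H||_F^2`` over the product of column-norm balls
    by cyclic exact minimization over columns: each column's subproblem is
    a norm-ball-constrained quadratic solved in closed form through the
    eigendecomposition of ``P^T P`` and a 1-D root-find on the Lagrange
    multiplier.  Warm-started at ``W_init`` and monotone in the surrogate.

    The constraint mirrors the one the last layer's dictionary carries;
    without it the joint objective has an unattained infimum along the
    rescaling direction ``W -> cW``, ``H -> H/c`` and alternating updates
    drift forever.
    """
    X = np.asarray(X, dtype=float)
    prefix = np.asarray(prefix, dtype=float)
    H = np.asarray(H, dtype=float)
    G_p = prefix.T @ prefix
    G_h = H @ H.T
    C = prefix.T @ X @ H.T
    sigma, U = np.linalg.eigh(G_p)
    sigma = np.clip(sigma, 0.0, None)

    W = np.asarray(W_init, dtype=float).copy()
    # start feasible: scale down any over-norm column
    norms = np.linalg.norm(W, axis=0)
    W /= np.maximum(norms, 1.0)

    k = W.shape[1]
    for _ in range(max_cycles):
        max_move = 0.0
        for j in range(k):
            q = G_h[j, j]
            # linear term of column j's subproblem with the others fixed
            b = C[:, j] - G_p @ (W @ G_h[:, j] - q * W[:, j])
            w_new = _ball_constrained_column(sigma, U, b, q, W[:, j])
            max_move = max(max_move, float(np.linalg.norm(w_new - W[:, j])))
            W[:, j] = w_new
        if max_move <= tol * max(1.0, float(np.linalg.norm(W))):
            break
    if not np.all(np.isfinite(W)):
        raise NumericalError("constrained basis update produced non-finite entries")
    return W


def _check_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    scale = max(1.0, float(np.abs(M).max()) if M.size else 1.0)
    if not np.allclose(M, M.T, rtol=0.0, atol=1e-10 * scale):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (M + M.T)


def solve_sylvester(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    B_eig: tuple | None = None,
) -> np.ndarray:
    """Solve ``A H + H B = C`` for symmetric PSD ``A`` (d x d) and ``B`` (n x n).

    Diagonalizing ``A = U diag(a) U^T`` and ``B = V diag(b) V^T`` turns the
    system into elementwise division: ``(U^T H V)_ij = (U^T C V)_ij / (a_i + b_j)``.
    The solution is unique iff no pair ``a_i + b_j`` vanishes.  The
    structurally singular case (both A and B singular — the graph Laplacian
    always has eigenvalue 0) is handled by a small ridge ``eps * I`` on A
    with ``eps = 1e-8 * trace(A)/d``, with a warning.

    Parameters
    ----------
    B_eig : (eigvals, eigvecs), optional
        Precomputed eigendecomposition of B (e.g. of ``alpha * L`` reused
        across sweeps; pass the decomposition of L and scale separately
        before calling, or of B itself).
    """
    A = _check_symmetric(np.asarray(A, dtype=float), "A")
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    d, n = A.shape[0], B.shape[0]
    if C.shape != (d, n):
        raise ValueError(f"C must be {d}x{n}; got {C.shape}")

    a, U = np.linalg.eigh(A)
    if B_eig is not None:
        b, V = B_eig
    else:
        B = _check_symmetric(B, "B")
        b, V = np.linalg.eigh(B)

    a = np.clip(a, 0.0, None)  # PSD by contract; clip eigh round-off
    b_min = float(b.min()) if n else 0.0
    tol_a = 1e-10 * max(1.0, float(a.max()) if d else 1.0)
    tol_b = 1e-10 * max(1.0, float(np.abs(b).max()) if n else 1.0)
    if a.min() <= tol_a and b_min <= tol_b:
        # shared (near-)zero eigenvalue: ridge jitter on A
        eps = 1e-8 * (np.trace(A) / d if np.trace(A) > 0 else 1.0)
        warnings.warn(
            f"Sylvester system structurally singular; adding ridge {eps:.3e} to A",
            stacklevel=2,
        )
        logger.debug("sylvester ridge jitter eps=%.3e", eps)
        a = a + eps

    denom = a[:, None] + b[None, :]
    if np.any(np.abs(denom) < 1e-14 * max(1.0, float(np.abs(denom).max()))):
        raise NumericalError("Sylvester system singular even after ridge jitter")

    H = U @ ((U.T @ C @ V) / denom) @ V.T

    resid = np.linalg.norm(A @ H + H @ B - C, "fro")
    bound = 1e-8 * (np.linalg.norm(A) + np.linalg.norm(B)) * np.linalg.norm(
        H, "fro"
    ) + 1e-10
    # the ridge itself perturbs the equation by eps*||H||; fold that in
    if a.min() > 0 and resid > bound + a.min() * np.linalg.norm(H, "fro"):
        raise NumericalError(
            f"Sylvester residual {resid:.3e} exceeds contract bound {bound:.3e}"
        )
    logger.debug("sylvester residual %.3e", resid)
    return H


def update_codes_intermediate(
    X: np.ndarray,
    prefix: np.ndarray,
    W: np.ndarray,
    L: np.ndarray,
    alpha: float,
    L_eig: tuple | None = None,
) -> np.ndarray:
    """Code update for an intermediate layer: the Sylvester stationary point.

    Solves ``(W^T P^T P W) H + H (alpha L) = W^T P^T X`` where P is the
    prefix product.  With ``alpha = 0`` this reduces to ordinary least
    squares against the projected target.

    Parameters
    ----------
    L_eig : (eigvals, eigvecs) of L, optional
        Reused across calls; scaled internally by ``alpha``.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    X = np.asarray(X, dtype=float)
    prefix = np.asarray(prefix, dtype=float)
    W = np.asarray(W, dtype=float)
    PW = prefix @ W
    A = PW.T @ PW
    C = PW.T @ X
    if alpha == 0.0:
        H = np.linalg.pinv(A, rcond=PINV_RCOND) @ C
        if not np.all(np.isfinite(H)):
            raise NumericalError("code update produced non-finite entries")
        return H
    B_eig = None
    if L_eig is not None:
        w, V = L_eig
        B_eig = (alpha * w, V)
    return solve_sylvester(A, alpha * np.asarray(L, dtype=float), C, B_eig=B_eig)
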