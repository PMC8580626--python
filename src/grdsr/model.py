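"""Fit orchestration for the deep graph-regularized sparse factorization.

The model approximates a feature-by-sample matrix ``X`` (m x n) by a
multilayer factorization ``X ~ W_1 W_2 ... W_l H_l`` with

    F = ||X - Lambda_{l-1} W_l H_l||_F^2
        + alpha * sum_{i=1..l} Tr(H_i L H_i^T)
        + beta  * sum_j ||(h_l)_j||_1,          s.t. ||w_j^i||^2 <= 1 for all i,

where ``Lambda_{i} = W_1 ... W_i`` and L is the kNN-graph Laplacian over
samples.  Intermediate layers carry auxiliary codes ``H_i`` tied to the
data through their own regularized least-squares problems; the last layer
is a constrained sparse-coding problem.  Every layer's basis carries the
unit-norm atom constraint: without it the objective has an unattained
infimum along the rescaling W -> cW, H -> H/c (the regularizers vanish in
the limit) and alternating updates drift along that valley forever.

Fitting is pretraining (layer-by-layer alternating solves) followed by
fine-tuning sweeps.  Each sweep proposes the closed-form /active-set block
updates in a fixed order (W_i then H_i for i ascending, then W_l then H_l)
and accepts a proposal only if the full objective F does not increase, so
the recorded objective trace is nonincreasing by construction.  The layer
subproblems optimize per-layer surrogates, not F itself, hence the explicit
acceptance check rather than a bare update.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import linear, sparse
from .exceptions import GrdsrError, NotFittedError
from .graph import SimilarityGraph, build_graph

__all__ = [
    "Hyperparams",
    "ModelState",
    "default_layer_sizes",
    "evaluate_objective",
    "pretrain",
    "fit",
    "reconstruct",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

# relative slack when testing whether a proposed block update increased F
_ACCEPT_RTOL = 1e-12
# the recorded trace must never rise by more than this relative amount
MONOTONE_RTOL = 1e-9


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def default_layer_sizes(m: int) -> list[int]:
    """Default two-layer architecture [round(m/2), round(m/4)], floors at 1."""
    return [max(1, _round_half_away(m / 2)), max(1, _round_half_away(m / 4))]


@dataclass
class Hyperparams:
    """Tunable parameters of the model.

    alpha : weight of the graph-smoothness penalty (>= 0).
    beta : weight of the last-layer L1 sparsity penalty (>= 0).
    layer_sizes : latent dimensions d_1..d_l; ``None`` means
        ``[round(m/2), round(m/4)]``.
    k, scheme, sigma : kNN-graph construction (see :mod:`grdsr.graph`).
    max_iter : cap on fine-tuning sweeps.
    tol : relative objective-change stopping threshold.
    n_pretrain_iter : alternations per layer during pretraining.
    seed : RNG seed for dictionary initialization.
    """

    alpha: float = 1e-2
    beta: float = 1e-1
    layer_sizes: list[int] | None = None
    k: int = 5
    scheme: str = "zero_one"
    sigma: float | None = None
    max_iter: int = 100
    tol: float = 1e-5
    n_pretrain_iter: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.layer_sizes is not None:
            self.layer_sizes = [int(d) for d in self.layer_sizes]
            if len(self.layer_sizes) == 0 or any(d < 1 for d in self.layer_sizes):
                raise ValueError("layer_sizes must be a nonempty list of positives")

    def resolved_layer_sizes(self, m: int) -> list[int]:
        return list(self.layer_sizes) if self.layer_sizes else default_layer_sizes(m)


@dataclass
class ModelState:
    """Fitted (or pretrained) factor stack plus bookkeeping."""

    Ws: list  # bases, Ws[i] is d_{i-1} x d_i
    Hs: list  # codes, Hs[i] is d_i x n
    hyperparams: Hyperparams
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    fitted: bool = False
    n_sweeps: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.Ws)

    def prefix(self, i: int) -> np.ndarray:
        """Prefix product Lambda_i = W_1 ... W_i (Lambda_0 = I)."""
        m = self.Ws[0].shape[0]
        P = np.eye(m)
        for W in self.Ws[:i]:
            P = P @ W
        return P


def evaluate_objective(
    X: np.ndarray,
    Ws: list,
    Hs: list,
    L: np.ndarray,
    alpha: float,
    beta: float,
) -> float:
    """Full objective F at the given factors (see module docstring)."""
    X = np.asarray(X, dtype=float)
    l = len(Ws)
    if l == 0 or len(Hs) != l:
        raise ValueError("need matching, nonempty lists of bases and codes")
    m, n = X.shape
    if Hs[-1].shape[1] != n or L.shape != (n, n):
        raise ValueError("factor/Laplacian shapes inconsistent with X")
    prefix = np.eye(m)
    for W in Ws[:-1]:
        prefix = prefix @ W
    rec = float(np.linalg.norm(X - prefix @ Ws[-1] @ Hs[-1], "fro") ** 2)
    smooth = sum(float(np.sum((H @ L) * H)) for H in Hs)
    l1 = float(np.abs(Hs[-1]).sum())
    return rec + alpha * smooth + beta * l1


def _objective(X, state: ModelState, L) -> float:
    hp = state.hyperparams
    return evaluate_objective(X, state.Ws, state.Hs, L, hp.alpha, hp.beta)


def _unit_column_init(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    W = rng.standard_normal((rows, cols))
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    return W / norms


def pretrain(
    X: np.ndarray,
    hyperparams: Hyperparams,
    graph: SimilarityGraph,
) -> ModelState:
    """Layer-by-layer initialization of the factor stack.

    Each intermediate layer alternates its pseudoinverse basis update and
    Sylvester code update against X through the current prefix product;
    the last layer alternates the dual dictionary update and feature-sign
    coding against the previous layer's codes.  Fully deterministic given
    the seed.
    """
    X = np.asarray(X, dtype=float)
    hp = hyperparams
    m, n = X.shape
    sizes = hp.resolved_layer_sizes(m)
    l = len(sizes)
    L = graph.L
    L_eig = graph.laplacian_eig()
    rng = np.random.default_rng(hp.seed)

    Ws: list = []
    Hs: list = []
    prefix = np.eye(m)
    d_prev = m
    try:
        for i in range(l - 1):
            W = _unit_column_init(rng, d_prev, sizes[i])
            H = linear.update_codes_intermediate(X, prefix, W, L, hp.alpha, L_eig=L_eig)
            for _ in range(hp.n_pretrain_iter):
                W = linear.update_basis_intermediate_constrained(
                    X, prefix, H, W, max_cycles=5
                )
                H = linear.update_codes_intermediate(
                    X, prefix, W, L, hp.alpha, L_eig=L_eig
                )
            Ws.append(W)
            Hs.append(H)
            prefix = prefix @ W
            d_prev = sizes[i]

        target = Hs[-1] if l > 1 else X
        W = _unit_column_init(rng, d_prev, sizes[-1])
        H = sparse.update_codes_feature_sign(target, W, L, hp.alpha, hp.beta)
        for _ in range(min(hp.n_pretrain_iter, 3)):
            if np.any(H):
                W = sparse.update_dictionary_dual(target, H)
            H = sparse.update_codes_feature_sign(
                target, W, L, hp.alpha, hp.beta, H_init=H
            )
        Ws.append(W)
        Hs.append(H)
    except GrdsrError as exc:
        raise type(exc)(f"pretraining failed at layer {len(Ws) + 1}: {exc}") from exc

    for idx, H in enumerate(Hs):
        if not np.all(np.isfinite(H)):
            raise GrdsrError(f"pretraining produced non-finite codes at layer {idx+1}")

    state = ModelState(Ws=Ws, Hs=Hs, hyperparams=hp)
    state.objective_trace = [_objective(X, state, L)]
    return state


def _try_accept(X, state, L, block_setter, proposal, current_obj):
    """Apply ``proposal`` via ``block_setter`` iff F does not increase."""
    backup = block_setter(proposal)
    new_obj = _objective(X, state, L)
    if new_obj <= current_obj * (1.0 + _ACCEPT_RTOL) + 1e-15:
        return min(new_obj, current_obj), True
    block_setter(backup)  # roll back
    return current_obj, False


def fit(
    X: np.ndarray,
    hyperparams: Hyperparams | None = None,
    graph: SimilarityGraph | None = None,
) -> ModelState:
    """Pretrain then fine-tune; returns the fitted :class:`ModelState`.

    Each sweep first proposes the layerwise updates in derivation order
    (intermediate bases/codes ascending, then last-layer dictionary and
    codes against the previous layer's codes), then runs a few cycles of
    exact block-coordinate descent on the full objective itself (bases
    against suffix products, last-layer codes against the composite
    dictionary).  Every proposal passes through an acceptance check, so
    ``objective_trace`` is nonincreasing by construction.  Stops when the
    relative objective change drops below ``tol`` or after ``max_iter``
    sweeps.
    """
    X = np.asarray(X, dtype=float)
    hp = hyperparams or Hyperparams()
    if graph is None:
        graph = build_graph(X, k=hp.k, scheme=hp.scheme, sigma=hp.sigma)
    L = graph.L
    L_eig = graph.laplacian_eig()

    state = pretrain(X, hp, graph)
    l = state.n_layers
    obj = state.objective_trace[0]

    def set_W(val, i):
        old = state.Ws[i]
        state.Ws[i] = val
        return old

    def set_H(val, i):
        old = state.Hs[i]
        state.Hs[i] = val
        return old

    for sweep in range(hp.max_iter):
        # (a) layerwise proposals in derivation order: each layer's own
        # surrogate solve, kept only if the full objective does not rise
        for i in range(l - 1):
            prefix = state.prefix(i)
            proposal = linear.update_basis_intermediate_constrained(
                X, prefix, state.Hs[i], state.Ws[i], max_cycles=10
            )
            obj, _ = _try_accept(X, state, L, lambda v, i=i: set_W(v, i), proposal, obj)
            proposal = linear.update_codes_intermediate(
                X, prefix, state.Ws[i], L, hp.alpha, L_eig=L_eig
            )
            obj, _ = _try_accept(X, state, L, lambda v, i=i: set_H(v, i), proposal, obj)

        target = state.Hs[l - 2] if l > 1 else X
        if np.any(state.Hs[-1]):
            proposal = sparse.update_dictionary_dual(target, state.Hs[-1])
            obj, _ = _try_accept(X, state, L, lambda v: set_W(v, l - 1), proposal, obj)
        proposal = sparse.update_codes_feature_sign(
            target, state.Ws[-1], L, hp.alpha, hp.beta, H_init=state.Hs[-1]
        )
        obj, _ = _try_accept(X, state, L, lambda v: set_H(v, l - 1), proposal, obj)

        # (b) exact block-coordinate refinement of the full objective:
        # each basis against its suffix product (the code matrix the deep
        # chain implies), then the last-layer codes against the composite
        # dictionary Lambda_{l-1} W_l with X itself as the target
        for _cycle in range(12):
            cycle_start = obj
            suffixes = [None] * l
            T = state.Hs[-1]
            for i in range(l - 1, -1, -1):
                suffixes[i] = T
                if i > 0:
                    T = state.Ws[i] @ T
            prefix = np.eye(X.shape[0])
            for i in range(l):
                proposal = linear.update_basis_intermediate_constrained(
                    X, prefix, suffixes[i], state.Ws[i], max_cycles=10
                )
                obj, _ = _try_accept(
                    X, state, L, lambda v, i=i: set_W(v, i), proposal, obj
                )
                prefix = prefix @ state.Ws[i]

            D = state.prefix(l - 1) @ state.Ws[-1]
            Hl = state.Hs[-1]
            sub = None
            for _ in range(8):
                Hl = sparse.update_codes_feature_sign(
                    X, D, L, hp.alpha, hp.beta, H_init=Hl
                )
                new_sub = sparse.sparse_layer_objective(
                    X, D, Hl, L, hp.alpha, hp.beta
                )
                if sub is not None and sub - new_sub <= 1e-8 * max(abs(sub), 1.0):
                    break
                sub = new_sub
            obj, _ = _try_accept(X, state, L, lambda v: set_H(v, l - 1), Hl, obj)
            if cycle_start - obj <= 1e-7 * max(cycle_start, 1.0):
                break

        prev = state.objective_trace[-1]
        state.objective_trace.append(obj)
        state.n_sweeps = sweep + 1
        if obj > prev * (1.0 + MONOTONE_RTOL):
            raise GrdsrError(
                f"internal consistency: objective rose {prev:.6e} -> {obj:.6e}"
            )
        rel_change = (prev - obj) / max(abs(prev), 1e-30)
        logger.info("sweep %d: objective %.6e (rel change %.3e)", sweep + 1, obj, rel_change)
        if rel_change < hp.tol:
            state.converged = True
            break

    state.fitted = True
    return state


def reconstruct(state: ModelState) -> np.ndarray:
    """Model reconstruction ``X' = Lambda_{l-1} W_l H_l``."""
    if not (state.fitted or state.objective_trace):
        raise NotFittedError("model has not been fitted")
    return state.prefix(state.n_layers - 1) @ state.Ws[-1] @ state.Hs[-1]


def save_model(state: ModelState, path) -> None:
    """Serialize factors, hyperparameters and trace to an NPZ archive."""
    arrays = {}
    for i, (W, H) in enumerate(zip(state.Ws, state.Hs)):
        arrays[f"W_{i}"] = W
        arrays[f"H_{i}"] = H
    meta = {
        "hyperparams": asdict(state.hyperparams),
        "converged": state.converged,
        "fitted": state.fitted,
        "n_sweeps": state.n_sweeps,
        "n_layers": state.n_layers,
    }
    arrays["objective_trace"] = np.asarray(state.objective_trace)
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> ModelState:
    """Inverse of :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        l = meta["n_layers"]
        Ws = [data[f"W_{i}"] for i in range(l)]
        Hs = [data[f"H_{i}"] for i in range(l)]
        trace = list(data["objective_trace"])
    state = ModelState(
        Ws=Ws,
        Hs=Hs,
        hyperparams=Hyperparams(**meta["hyperparams"]),
        objective_trace=trace,
        converged=meta["converged"],
        fitted=meta["fitted"],
        n_sweeps=meta["n_sweeps"],
    )
    return state


def export_trace_tsv(state: ModelState, path) -> None:
    """Objective trace as two-column TSV (sweep, objective)."""
    rows = np.column_stack(
        [np.arange(len(state.objective_trace)), np.asarray(state.objective_trace)]
    )
    np.savetxt(path, rows, delimiter="\t", header="sweep\tobjective", comments="")
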