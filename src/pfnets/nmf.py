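"""Spatially regularized, group-consensus non-negative matrix factorization.

Each subject's preprocessed timeseries ``X^i`` (time x vertex, values in
[0, 1]) is factorized as ``X^i ~ U^i (V^i)'`` with nonnegative network time
courses ``U^i`` (T x K) and loadings ``V^i`` (S x K).  Two penalties shape
the solution:

* a **locality** term ``Tr((V^i)' L V^i)`` on the graph Laplacian of a
  neighbor-restricted timeseries-affinity graph, encouraging spatially
  smooth, functionally coherent parcels;
* a **group-consensus** term, an L2,1 group-sparsity ratio over each network
  column stacked across subjects, pulling corresponding networks toward a
  shared topography.

The joint objective is

    sum_i ||X^i - U^i (V^i)'||_F^2 + lambda_M sum_i Tr((V^i)' L^i V^i)
                                   + lambda_c R_c,
    s.t. U^i, V^i >= 0,  max_s V^i[s, k] = 1,

with lambda_M = beta * T / (K * n_m) and lambda_c = alpha * n * T / K.

Optimization uses multiplicative updates (graph-regularized V step; the
consensus term contributes its positive/negative subgradient parts).  A
geometric backtracking safeguard keeps the tracked objective non-increasing.
The max-norm constraint is applied at convergence with the compensating
scale folded into U, leaving the reconstruction unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .synthetic import SurfaceMesh

__all__ = [
    "NmfConfig",
    "AffinityGraph",
    "NmfResult",
    "preprocess_for_nmf",
    "build_affinity",
    "consensus_penalty",
    "locality_penalty",
    "regularization_weights",
    "objective",
    "fit_group_nmf",
    "fit_multisubject_nmf",
]

_EPS = 1e-12


@dataclass
class NmfConfig:
    K: int
    alpha: float = 1.0
    beta: float = 10.0
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class AffinityGraph:
    W: sp.csr_matrix     # nonnegative symmetric, zero off neighbor pairs
    D: np.ndarray        # degree vector
    L: sp.csr_matrix     # D - W, positive semidefinite


@dataclass
class NmfResult:
    U: np.ndarray
    V: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    column_scales: np.ndarray = field(default_factory=lambda: np.empty(0))


def preprocess_for_nmf(X: np.ndarray) -> np.ndarray:
    """Shift each vertex timeseries to its minimum and normalize to its
    maximum so values lie in [0, 1]; constant vertices map to all-zeros."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("timeseries contains non-finite values")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    shifted = X - X.min(axis=0, keepdims=True)
    peak = shifted.max(axis=0, keepdims=True)
    peak[peak == 0] = 1.0  # constant vertex -> zeros
    return shifted / peak


def build_affinity(mesh: SurfaceMesh, X: np.ndarray) -> AffinityGraph:
    """Neighbor-pair affinity (1 + Pearson(X_a, X_b)) / 2; zero elsewhere.

    A zero-variance vertex has undefined correlation; its edges take the
    uninformative limit 0.5.
    """
    S = mesh.n_vertices
    if X.shape[1] != S:
        raise ValueError("timeseries does not match mesh")
    Z = X - X.mean(axis=0, keepdims=True)
    sd = Z.std(axis=0)
    safe = sd.copy()
    safe[safe == 0] = 1.0
    Z = Z / safe
    rows, cols, vals = [], [], []
    T = X.shape[0]
    for a in range(S):
        for b in mesh.neighbors[a]:
            if b <= a:
                continue
            if sd[a] == 0 or sd[b] == 0:
                w = 0.5
            else:
                r = float(Z[:, a] @ Z[:, b]) / T
                w = (1.0 + np.clip(r, -1.0, 1.0)) / 2.0
            rows += [a, b]
            cols += [b, a]
            vals += [w, w]
    W = sp.csr_matrix((vals, (rows, cols)), shape=(S, S))
    D = np.asarray(W.sum(axis=1)).ravel()
    L = sp.csr_matrix(sp.diags(D) - W)
    return AffinityGraph(W=W, D=D, L=L)


def consensus_penalty(Vs: list[np.ndarray]) -> float:
    """Group-sparsity ratio over subject-stacked network columns:
    R_c = sum_k [sum_s sqrt(sum_i V_isk^2)] / sqrt(sum_s sum_i V_isk^2).
    All-zero columns contribute 0."""
    stack = np.stack(Vs)  # (n, S, K)
    g = np.sqrt((stack ** 2).sum(axis=0))          # (S, K)
    num = g.sum(axis=0)                            # (K,)
    den = np.sqrt((g ** 2).sum(axis=0))            # (K,)
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return float(out.sum())


def locality_penalty(V: np.ndarray, L: sp.spmatrix) -> float:
    """Tr(V' L V) = sum over edges W_ab * sum_k (V_ak - V_bk)^2."""
    return float(np.sum(V * (L @ V)))


def regularization_weights(config: NmfConfig, n: int, T: int,
                           n_m: float) -> tuple[float, float]:
    """lambda_M = beta * T / (K * n_m); lambda_c = alpha * n * T / K."""
    lam_M = config.beta * T / (config.K * n_m)
    lam_c = config.alpha * n * T / config.K
    return lam_M, lam_c


def objective(Xs: list[np.ndarray], Us: list[np.ndarray], Vs: list[np.ndarray],
              Ls: list[sp.spmatrix], lam_M: float, lam_c: float) -> float:
    """Joint objective: reconstruction + weighted locality + weighted consensus."""
    total = 0.0
    for X, U, V, L in zip(Xs, Us, Vs, Ls):
        R = X - U @ V.T
        total += float(np.sum(R * R)) + lam_M * locality_penalty(V, L)
    if lam_c > 0:
        total += lam_c * consensus_penalty(Vs)
    return total


def _update_U(X: np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    num = X @ V
    den = U @ (V.T @ V) + _EPS
    return U * (num / den)


def _rescale_to_maxnorm(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    scales = V.max(axis=0)
    scales[scales == 0] = 1.0
    return U * scales, V / scales, scales


def fit_group_nmf(X_concat: np.ndarray, graph: AffinityGraph, config: NmfConfig,
                  init: tuple[np.ndarray, np.ndarray] | None = None,
                  lam_M: float | None = None, n_m: float | None = None,
                  subject_T: int | None = None) -> NmfResult:
    """Single pooled decomposition (no consensus term): alternating
    multiplicative updates minimizing reconstruction + lam_M * Tr(V'LV).

    ``subject_T`` is the per-subject scan length entering the lambda_M
    scaling rule; by default the matrix's own row count is used (appropriate
    when ``X_concat`` is one subject)."""
    X = np.asarray(X_concat, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be nonnegative (preprocess first)")
    T, S = X.shape
    if config.K > min(T, S):
        raise ValueError("K exceeds min(timepoints, vertices)")
    if lam_M is None:
        nm = n_m if n_m is not None else float(np.mean(np.diff(graph.W.indptr)))
        lam_M, _ = regularization_weights(config, n=1, T=subject_T or T,
                                          n_m=max(nm, 1.0))
    rng = np.random.default_rng(config.seed)
    if init is None:
        U = rng.uniform(0.01, 1.0, (T, config.K))
        V = rng.uniform(0.01, 1.0, (S, config.K))
    else:
        U, V = (np.array(init[0], dtype=float), np.array(init[1], dtype=float))
    W, D, L = graph.W, graph.D, graph.L

    def obj(Uc, Vc):
        R = X - Uc @ Vc.T
        return float(np.sum(R * R)) + lam_M * locality_penalty(Vc, L)

    trace = [obj(U, V)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        U = _update_U(X, U, V)
        num = X.T @ U + lam_M * (W @ V)
        den = V @ (U.T @ U) + lam_M * (D[:, None] * V) + _EPS
        V_cand = V * (num / den)
        f = obj(U, V_cand)
        if f > trace[-1] + 1e-10 * max(1.0, abs(trace[-1])):
            V_cand, f = _backtrack(V, V_cand, lambda Vt: obj(U, Vt), trace[-1])
        V = V_cand
        trace.append(f)
        rel = abs(trace[-2] - trace[-1]) / max(abs(trace[-2]), _EPS)
        if rel < config.tol:
            converged = True
            break
    U, V, scales = _rescale_to_maxnorm(U, V)
    return NmfResult(U=U, V=V, objective_trace=np.array(trace), n_iter=it,
                     converged=converged, column_scales=scales)


def _backtrack(V_old: np.ndarray, V_new: np.ndarray, f, f_prev: float,
               max_halvings: int = 6) -> tuple[np.ndarray, float]:
    """Geometric interpolation toward the previous iterate until the
    objective stops increasing; falls back to the previous iterate."""
    ratio = (V_new + _EPS) / (V_old + _EPS)
    t = 0.5
    for _ in range(max_halvings):
        V_t = V_old * ratio ** t
        f_t = f(V_t)
        if f_t <= f_prev + 1e-12 * max(1.0, abs(f_prev)):
            return V_t, f_t
        t *= 0.5
    return V_old, f_prev


def fit_multisubject_nmf(Xs: list[np.ndarray], graphs: list[AffinityGraph],
                         config: NmfConfig, init_V: np.ndarray,
                         init_Vs: list[np.ndarray] | None = None,
                         anchor_V: np.ndarray | None = None,
                         lam_M: float | None = None,
                         lam_c: float | None = None) -> tuple[list[NmfResult], np.ndarray]:
    """Joint fit over subjects: per-subject reconstruction and locality plus
    the cross-subject consensus term.  Each subject's loadings start at
    ``init_V`` (the group atlas) unless ``init_Vs`` overrides per subject.
    ``anchor_V``, when given, joins the consensus stack as a fixed member so
    single-subject fits stay anchored to the atlas topography."""
    n = len(Xs)
    S = Xs[0].shape[1]
    for X in Xs:
        if X.shape[1] != S:
            raise ValueError("all subjects must share the same vertex count")
        if np.any(X < 0):
            raise ValueError("X must be nonnegative (preprocess first)")
    T = Xs[0].shape[0]
    nm = float(np.mean(np.diff(graphs[0].W.indptr)))
    auto_M, auto_c = regularization_weights(config, n=n, T=T, n_m=max(nm, 1.0))
    lam_M = auto_M if lam_M is None else lam_M
    lam_c = auto_c if lam_c is None else lam_c

    rng = np.random.default_rng(config.seed)
    Us = [rng.uniform(0.01, 1.0, (X.shape[0], config.K)) for X in Xs]
    if init_Vs is not None:
        Vs = [np.array(V, dtype=float) for V in init_Vs]
    else:
        Vs = [np.array(init_V, dtype=float) for _ in range(n)]

    Ls = [g.L for g in graphs]

    def consensus_stack(Vlist):
        stack = [v for v in Vlist]
        if anchor_V is not None:
            stack = stack + [anchor_V]
        return stack

    def total_obj(Ulist, Vlist):
        val = 0.0
        for X, U, V, L in zip(Xs, Ulist, Vlist, Ls):
            R = X - U @ V.T
            val += float(np.sum(R * R)) + lam_M * locality_penalty(V, L)
        if lam_c > 0:
            val += lam_c * consensus_penalty(consensus_stack(Vlist))
        return val

    trace = [total_obj(Us, Vs)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        Us = [_update_U(X, U, V) for X, U, V in zip(Xs, Us, Vs)]
        # consensus statistics over the stacked columns
        stack = np.stack(consensus_stack(Vs))       # (n[+1], S, K)
        g = np.sqrt((stack ** 2).sum(axis=0))        # (S, K)
        num = g.sum(axis=0)                          # (K,)
        den = np.sqrt((g ** 2).sum(axis=0))          # (K,)
        den = np.where(den > 0, den, 1.0)
        pos_coef = num / den ** 3                    # multiplies V in numerator
        inv_gden = 1.0 / (g * den[None, :] + _EPS)   # multiplies V in denominator
        V_cands = []
        for X, U, V, graph in zip(Xs, Us, Vs, graphs):
            numer = X.T @ U + lam_M * (graph.W @ V) + lam_c * pos_coef[None, :] * V
            denom = (V @ (U.T @ U) + lam_M * (graph.D[:, None] * V)
                     + lam_c * V * inv_gden + _EPS)
            V_cands.append(V * (numer / denom))
        f = total_obj(Us, V_cands)
        if f > trace[-1] + 1e-10 * max(1.0, abs(trace[-1])):
            # damp all subjects' V steps jointly
            t = 0.5
            accepted = False
            ratios = [(Vc + _EPS) / (V + _EPS) for Vc, V in zip(V_cands, Vs)]
            for _ in range(6):
                V_t = [V * r ** t for V, r in zip(Vs, ratios)]
                f_t = total_obj(Us, V_t)
                if f_t <= trace[-1] + 1e-12 * max(1.0, abs(trace[-1])):
                    V_cands, f, accepted = V_t, f_t, True
                    break
                t *= 0.5
            if not accepted:
                V_cands, f = Vs, trace[-1]
        Vs = V_cands
        trace.append(f)
        rel = abs(trace[-2] - trace[-1]) / max(abs(trace[-2]), _EPS)
        if rel < config.tol:
            converged = True
            break

    results = []
    for U, V in zip(Us, Vs):
        U2, V2, scales = _rescale_to_maxnorm(U.copy(), V.copy())
        results.append(NmfResult(U=U2, V=V2, objective_trace=np.array(trace),
                                 n_iter=it, converged=converged,
                                 column_scales=scales))
    return results, np.array(trace)
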