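"""Group-consensus atlas construction and per-subject personalization.

The group atlas at each scale K is built robustly: many bootstrap
decompositions of random subject subsets are fused by normalized-cut
spectral clustering of network-to-network similarity, and each cluster's
most representative network is kept.  Personalization then re-optimizes the
joint NMF for one subject, initialized at (and consensus-anchored to) the
fused atlas, so network identity is preserved across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import SpectralClustering
from sklearn.metrics import adjusted_rand_score

from .nmf import AffinityGraph, NmfConfig, NmfResult, build_affinity, fit_group_nmf, fit_multisubject_nmf
from .synthetic import SurfaceMesh

__all__ = [
    "AtlasSimilarity",
    "GroupAtlas",
    "bootstrap_group_atlases",
    "network_similarity",
    "fuse_atlases",
    "personalize",
    "hard_partition",
    "nestedness_vs_k2",
    "adjusted_rand",
    "best_match_correlation",
]

UNASSIGNED = -1


@dataclass
class AtlasSimilarity:
    """Pairwise network similarity S = exp(-d^2 / sigma^2) with
    d = 1 - Pearson(loading_i, loading_j) and sigma the median off-diagonal d."""

    d: np.ndarray
    sigma: float
    S_sim: np.ndarray


@dataclass
class GroupAtlas:
    """Fused consensus loadings (S x K) plus provenance of each column:
    (replicate index, column index) of the representative network."""

    V: np.ndarray
    scale: int
    provenance: list[tuple[int, int]]


def bootstrap_group_atlases(subjects: list[np.ndarray], mesh: SurfaceMesh, K: int,
                            n_subset: int, n_reps: int, config: NmfConfig,
                            seed: int, subject_T: int | None = None) -> list[np.ndarray]:
    """n_reps random-init group decompositions, each on the temporal
    concatenation of a random subject subset.  ``subjects`` are preprocessed
    (nonnegative, [0, 1]) time x vertex matrices."""
    if n_reps < 2:
        raise ValueError("need n_reps >= 2 for fusion")
    if n_subset > len(subjects):
        raise ValueError("n_subset exceeds available subjects")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_reps):
        idx = rng.choice(len(subjects), size=n_subset, replace=False)
        X = np.vstack([subjects[i] for i in idx])
        graph = build_affinity(mesh, X)
        cfg = NmfConfig(K=K, alpha=config.alpha, beta=config.beta,
                        max_iter=config.max_iter, tol=config.tol,
                        seed=int(rng.integers(0, 2**31 - 1)))
        res = fit_group_nmf(X, graph, cfg, subject_T=subject_T)
        out.append(res.V)
    return out


def network_similarity(V_stacked: np.ndarray) -> AtlasSimilarity:
    """Distances and similarities among stacked networks (rows = networks)."""
    R = np.corrcoef(V_stacked)
    d = 1.0 - np.clip(R, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    off = d[np.triu_indices_from(d, k=1)]
    sigma = float(np.median(off))
    if sigma <= 0:
        sigma = 1.0  # all networks identical; similarity saturates at 1
    S_sim = np.exp(-(d ** 2) / sigma ** 2)
    return AtlasSimilarity(d=d, sigma=sigma, S_sim=S_sim)


def fuse_atlases(atlases: list[np.ndarray], K: int, seed: int = 0) -> GroupAtlas:
    """Normalized-cut spectral clustering of the n_reps*K stacked networks
    into K clusters; each cluster's representative maximizes summed
    within-cluster similarity (self-similarity excluded)."""
    n_reps = len(atlases)
    stacked = np.hstack(atlases).T          # (n_reps*K, S)
    if stacked.shape[0] != n_reps * K:
        raise ValueError("stacked network count != n_reps * K")
    sim = network_similarity(stacked)
    labels = None
    for attempt in range(5):
        sc = SpectralClustering(n_clusters=K, affinity="precomputed",
                                assign_labels="kmeans",
                                random_state=seed + attempt)
        cand = sc.fit_predict(sim.S_sim)
        if len(np.unique(cand)) == K:
            labels = cand
            break
    if labels is None:
        raise RuntimeError("spectral clustering produced an empty cluster in 5 attempts")
    reps = []
    for c in range(K):
        members = np.flatnonzero(labels == c)
        within = sim.S_sim[np.ix_(members, members)].sum(axis=1) - 1.0  # drop self
        reps.append(int(members[np.argmax(within)]))
    reps.sort()  # deterministic column order by stacked index
    V = stacked[reps].T.copy()
    colmax = V.max(axis=0, keepdims=True)
    colmax[colmax == 0] = 1.0
    V = V / colmax
    provenance = [(r // K, r % K) for r in reps]
    return GroupAtlas(V=V, scale=K, provenance=provenance)


def personalize(subject_ts: np.ndarray, graph: AffinityGraph, atlas: GroupAtlas,
                config: NmfConfig) -> NmfResult:
    """Subject-specific loadings: single-subject joint fit initialized at and
    consensus-anchored to the group atlas."""
    results, _ = fit_multisubject_nmf([subject_ts], [graph], config,
                                      init_V=atlas.V, anchor_V=atlas.V)
    return results[0]


def hard_partition(V: np.ndarray) -> np.ndarray:
    """Per-vertex label = argmax loading; ties break to the lowest network
    index (numpy argmax convention); all-zero rows are UNASSIGNED (-1)."""
    labels = np.argmax(V, axis=1).astype(np.intp)
    labels[np.all(V == 0, axis=1)] = UNASSIGNED
    return labels


def nestedness_vs_k2(partition_k2: np.ndarray, partition_K: np.ndarray
                     ) -> tuple[list[tuple[int, int, float]], dict[int, float]]:
    """For each network at the finer scale: the coarse (K=2) parent holding
    the plurality of its vertices and the plurality share.  Summary maps each
    parent to the percentage of finer networks assigned to it."""
    nets = np.unique(partition_K[partition_K != UNASSIGNED])
    rows = []
    for k in nets:
        idx = partition_K == k
        parents = partition_k2[idx]
        parents = parents[parents != UNASSIGNED]
        counts = np.bincount(parents, minlength=2)
        parent = int(np.argmax(counts))  # tie -> lower label
        frac = counts[parent] / counts.sum() if counts.sum() else np.nan
        rows.append((int(k), parent, float(frac)))
    summary = {}
    for parent in (0, 1):
        summary[parent] = 100.0 * sum(1 for _, p, _ in rows if p == parent) / len(rows)
    return rows, summary


def adjusted_rand(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Permutation-model adjusted Rand index in [-1, 1]."""
    return float(adjusted_rand_score(labels_a, labels_b))


def best_match_correlation(V_a: np.ndarray, V_b: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian assignment of columns of V_a to V_b maximizing total loading
    correlation; returns (assignment for each column of V_a, matched corrs)."""
    Ka, Kb = V_a.shape[1], V_b.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(V_a.T, V_b.T)[:Ka, Ka:]
    C = np.nan_to_num(C)
    r, c = linear_sum_assignment(-C)
    order = np.argsort(r)
    return c[order], C[r, c][order]
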