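"""Between-network coupling and topographic-variability summaries.

Coupling is plain Pearson correlation of BOLD timeseries aggregated at three
levels under each subject's hard network partition:

* edge level — mean vertex-by-vertex correlation between all cross pairs of
  two networks (the diagonal stores the within-network mean, informational);
* network level — a network's mean coupling to all other networks
  (off-diagonal row mean of the edge matrix);
* vertex level — each vertex's mean correlation to vertices outside its own
  network.

Correlations are averaged raw (no Fisher transform).  Hierarchy summaries
(per-network mean gradient value, absolute between-network hierarchical
distance, mean Euclidean distance) use the group-consensus partition.
Topographic variability is the median absolute deviation (MAD) of loadings
across subjects, averaged over networks per scale.
"""

from __future__ import annotations

import numpy as np

from .atlas import UNASSIGNED
from .synthetic import SurfaceMesh

__all__ = [
    "edge_coupling",
    "network_coupling",
    "vertex_coupling",
    "network_hierarchy_values",
    "hierarchical_distance",
    "euclidean_edge_distance",
    "mad_map",
]


def _corr_matrix(ts: np.ndarray) -> np.ndarray:
    Z = ts - ts.mean(axis=0, keepdims=True)
    sd = Z.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = Z / sd_safe
    R = (Z.T @ Z) / ts.shape[0]
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def edge_coupling(ts: np.ndarray, labels: np.ndarray, K: int | None = None) -> np.ndarray:
    """K x K matrix of mean cross-network vertex-pair correlations.

    Cell (A, B), A != B: mean Pearson over all pairs (a in A, b in B).
    Diagonal: within-network mean pairwise correlation (self-pairs excluded;
    singleton networks get NaN there).  Empty networks propagate NaN.
    """
    if K is None:
        K = int(labels[labels != UNASSIGNED].max()) + 1 if np.any(labels != UNASSIGNED) else 0
    R = _corr_matrix(ts)
    out = np.full((K, K), np.nan)
    members = [np.flatnonzero(labels == k) for k in range(K)]
    for a in range(K):
        if members[a].size == 0:
            continue
        for b in range(a, K):
            if members[b].size == 0:
                continue
            block = R[np.ix_(members[a], members[b])]
            if a == b:
                m = members[a].size
                if m < 2:
                    continue
                val = (np.nansum(block) - m) / (m * m - m)
            else:
                val = float(np.nanmean(block))
            out[a, b] = out[b, a] = val
    return out


def network_coupling(edge_matrix: np.ndarray) -> np.ndarray:
    """Per-network mean coupling to all other networks (NaN-aware)."""
    K = edge_matrix.shape[0]
    out = np.full(K, np.nan)
    for k in range(K):
        row = np.delete(edge_matrix[k], k)
        if np.any(np.isfinite(row)):
            out[k] = np.nanmean(row)
    return out


def vertex_coupling(ts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-vertex mean correlation to all vertices outside its own network.

    Unassigned vertices get NaN.
    """
    R = _corr_matrix(ts)
    S = ts.shape[1]
    out = np.full(S, np.nan)
    for v in range(S):
        if labels[v] == UNASSIGNED:
            continue
        others = (labels != labels[v]) & (labels != UNASSIGNED)
        if others.any():
            out[v] = np.nanmean(R[v, others])
    return out


def network_hierarchy_values(group_partition: np.ndarray,
                             hierarchy_map: np.ndarray,
                             K: int | None = None) -> np.ndarray:
    """Per-network mean hierarchy value over the group-consensus partition."""
    if K is None:
        K = int(group_partition[group_partition != UNASSIGNED].max()) + 1
    out = np.full(K, np.nan)
    for k in range(K):
        idx = group_partition == k
        if idx.any():
            out[k] = hierarchy_map[idx].mean()
    return out


def hierarchical_distance(h_net: np.ndarray) -> np.ndarray:
    """Edge-level absolute difference of network hierarchy positions."""
    return np.abs(h_net[:, None] - h_net[None, :])


def euclidean_edge_distance(mesh: SurfaceMesh, group_partition: np.ndarray,
                            K: int | None = None) -> np.ndarray:
    """K x K mean pairwise 3D Euclidean distance between member vertices."""
    if K is None:
        K = int(group_partition[group_partition != UNASSIGNED].max()) + 1
    out = np.full((K, K), np.nan)
    members = [np.flatnonzero(group_partition == k) for k in range(K)]
    for a in range(K):
        if members[a].size == 0:
            continue
        for b in range(a, K):
            if members[b].size == 0:
                continue
            diff = mesh.coords[members[a]][:, None, :] - mesh.coords[members[b]][None, :, :]
            out[a, b] = out[b, a] = float(np.linalg.norm(diff, axis=2).mean())
    return out


def mad_map(Vs_across_subjects: list[np.ndarray], zscore: bool = False) -> np.ndarray:
    """Per-vertex topographic variability at one scale.

    MAD (no consistency constant) of each network's loading across subjects,
    averaged over the K networks; optionally z-scored across vertices.
    """
    if len(Vs_across_subjects) < 3:
        raise ValueError("MAD needs at least 3 subjects")
    stack = np.stack(Vs_across_subjects)            # (n, S, K)
    med = np.median(stack, axis=0)
    mad = np.median(np.abs(stack - med), axis=0)    # (S, K)
    out = mad.mean(axis=1)
    if zscore:
        sd = out.std()
        out = (out - out.mean()) / (sd if sd > 0 else 1.0)
    return out
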