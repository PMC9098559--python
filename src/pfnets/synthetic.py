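"""Synthetic cortical-surface cohort generator.

Everything downstream of raw data acquisition operates on (i) per-subject
time x vertex BOLD-like matrices on a shared spherical surface mesh, (ii) a
per-vertex functional-hierarchy map (unimodal -> transmodal continuum), and
(iii) cohort covariates.  Real developmental-cohort data are protected, so
this module plants the structure the pipeline is meant to recover:

* nested multi-scale spatially contiguous networks (recursive bisection of
  a two-network split, distance-kernel soft loadings),
* subject-specific topographic perturbation whose magnitude grows along the
  hierarchy map (association cortex analog varies most),
* between-network coupling with a hierarchical-distance gradient plus
  per-edge age slopes that are negative for hierarchically distant edges and
  positive for short unimodal edges,
* an executive-function (EF) score assembled from edge couplings with
  weights that are positive mid-hierarchy and negative at both extremes,
  plus an age trend and noise.

All randomness flows through one ``numpy.random.Generator`` per operation,
so identical config + seed reproduces bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.cluster.vq import kmeans2

__all__ = [
    "SurfaceMesh",
    "GroundTruth",
    "PlantedCouplingModel",
    "SyntheticConfig",
    "build_sphere_mesh",
    "make_hierarchy_map",
    "make_group_networks",
    "personalize_ground_truth",
    "make_cohort",
    "network_hierarchy_from_loadings",
    "planted_coupling_model",
    "planted_coupling_matrix",
    "repair_correlation",
    "simulate_timeseries",
    "sample_empirical_coupling",
    "make_ef_scores",
    "ef_edge_weights",
    "generate_dataset",
]

REFERENCE_AGE = 15.5  # cohort midpoint, years


@dataclass(frozen=True)
class SurfaceMesh:
    """Icosphere proxy for a spherical cortical-surface projection.

    ``coords`` are unit-norm 3-vectors, ``neighbors`` the triangle-edge
    adjacency (symmetric; every vertex has >= 3 neighbors).
    """

    coords: np.ndarray                  # (S, 3)
    neighbors: tuple[np.ndarray, ...]   # per-vertex sorted neighbor indices
    faces: np.ndarray                   # (F, 3) for export

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def mean_neighbor_count(self) -> float:
        return float(np.mean([len(nb) for nb in self.neighbors]))

    def validate(self) -> None:
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("mesh coordinates must be unit-norm")
        for v, nb in enumerate(self.neighbors):
            if len(nb) < 3:
                raise ValueError(f"vertex {v} has fewer than 3 neighbors")
            for u in nb:
                if v not in self.neighbors[u]:
                    raise ValueError("neighbor relation not symmetric")


def build_sphere_mesh(subdivisions: int) -> SurfaceMesh:
    """Icosphere with ``10 * 4**subdivisions + 2`` vertices."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    coords = np.asarray(m.vertices, dtype=float)
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    neighbors = tuple(
        np.array(sorted(m.vertex_neighbors[v]), dtype=np.intp)
        for v in range(coords.shape[0])
    )
    return SurfaceMesh(coords=coords, neighbors=neighbors,
                       faces=np.asarray(m.faces, dtype=np.intp))


def _smooth_on_mesh(values: np.ndarray, mesh: SurfaceMesh, n_iter: int) -> np.ndarray:
    out = values.astype(float).copy()
    for _ in range(n_iter):
        nb_mean = np.array([out[nb].mean() for nb in mesh.neighbors])
        out = 0.5 * out + 0.5 * nb_mean
    return out


def make_hierarchy_map(mesh: SurfaceMesh, seed: int, noise_sd: float = 0.3,
                       n_smooth: int = 10) -> np.ndarray:
    """Smooth scalar field standing in for the principal functional gradient.

    Base signal is the z-coordinate (one pole unimodal, the other
    transmodal) plus mesh-smoothed Gaussian noise, rescaled to [0, 1].
    """
    rng = np.random.default_rng(seed)
    base = mesh.coords[:, 2].copy()
    if noise_sd > 0:
        noise = _smooth_on_mesh(rng.normal(0.0, 1.0, mesh.n_vertices), mesh, n_smooth)
        sd = noise.std()
        if sd > 0:
            base = base + noise_sd * noise / sd
    lo, hi = base.min(), base.max()
    return (base - lo) / (hi - lo)


def _recursive_bisection(mesh: SurfaceMesh, K: int, seed: int) -> np.ndarray:
    """Split the sphere into K regions by recursively bisecting the largest
    region with seeded 2-means on vertex coordinates.  The first split is the
    K=2 bipartition; later networks therefore nest inside its halves."""
    labels = np.zeros(mesh.n_vertices, dtype=np.intp)
    rng = np.random.default_rng(seed)
    next_label = 1
    while next_label < K:
        sizes = np.bincount(labels, minlength=next_label)
        target = int(np.argmax(sizes))
        idx = np.flatnonzero(labels == target)
        pts = mesh.coords[idx]
        # deterministic farthest-pair init avoids empty clusters
        d = pts @ pts.T
        a, b = np.unravel_index(np.argmin(d), d.shape)
        centroids, sub = kmeans2(pts, pts[[a, b]], minit="matrix", seed=rng)
        if len(np.unique(sub)) < 2:  # pragma: no cover - farthest pair prevents this
            half = len(idx) // 2
            sub = np.zeros(len(idx), dtype=int)
            sub[half:] = 1
        labels[idx[sub == 1]] = next_label
        next_label += 1
    return labels


def make_group_networks(mesh: SurfaceMesh, K: int, seed: int,
                        kernel_width: float = 0.8) -> np.ndarray:
    """Planted group atlas: K contiguous soft parcels, column max 1.

    Loadings are Gaussian kernels of great-circle angle to each region
    centroid; ``kernel_width`` multiplies the region's angular radius.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    labels = _recursive_bisection(mesh, K, seed)
    V = np.zeros((mesh.n_vertices, K))
    for k in range(K):
        idx = np.flatnonzero(labels == k)
        c = mesh.coords[idx].mean(axis=0)
        c /= np.linalg.norm(c)
        ang = np.arccos(np.clip(mesh.coords @ c, -1.0, 1.0))
        radius = max(float(ang[idx].mean()), 1e-3)
        V[:, k] = np.exp(-0.5 * (ang / (kernel_width * radius)) ** 2)
    V /= V.max(axis=0, keepdims=True)
    return V


def personalize_ground_truth(groupV: np.ndarray, hierarchy: np.ndarray,
                             topo_sd: float, seed: int) -> np.ndarray:
    """Subject-specific loadings: multiplicative vertex-wise perturbation with
    standard deviation ``topo_sd * hierarchy``, clipped nonnegative and
    re-max-normalized.  Topographic variability therefore grows along the
    hierarchy, the association-cortex pattern seen in real cohorts."""
    rng = np.random.default_rng(seed)
    sd = topo_sd * hierarchy[:, None]
    factor = np.clip(1.0 + rng.normal(0.0, 1.0, groupV.shape) * sd, 0.0, None)
    V = groupV * factor
    colmax = V.max(axis=0, keepdims=True)
    colmax[colmax == 0] = 1.0
    return V / colmax


def make_cohort(n: int, age_range: tuple[float, float] = (8.0, 23.0),
                seed: int = 0) -> pd.DataFrame:
    """Cohort table: uniform ages, Bernoulli(0.5) sex, lognormal motion."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "age": rng.uniform(age_range[0], age_range[1], n),
        "sex": rng.integers(0, 2, n),
        "motion": rng.lognormal(mean=np.log(0.08), sigma=0.4, size=n),
    })


def network_hierarchy_from_loadings(V: np.ndarray, hierarchy: np.ndarray) -> np.ndarray:
    """Mean hierarchy value over each network's argmax vertices."""
    labels = np.argmax(V, axis=1)
    K = V.shape[1]
    out = np.empty(K)
    for k in range(K):
        idx = labels == k
        out[k] = hierarchy[idx].mean() if idx.any() else np.nan
    return out


@dataclass(frozen=True)
class PlantedCouplingModel:
    """Edge-level generative model of between-network coupling.

    target(edge, age) = intercept - dist_slope * D_e + b_e * (age - age0)
    where D_e is hierarchical distance and b_e the per-edge age slope.
    """

    h_net: np.ndarray        # (K,) network hierarchy positions
    intercept: float
    dist_slope: float
    age_slopes: np.ndarray   # (K, K) symmetric, zero diagonal
    age0: float = REFERENCE_AGE

    @property
    def h_dist(self) -> np.ndarray:
        return np.abs(self.h_net[:, None] - self.h_net[None, :])


def planted_coupling_model(h_net: np.ndarray, intercept: float = 0.35,
                           dist_slope: float = 0.3,
                           age_dist_slope: float = 0.02,
                           age_hierarchy_slope: float = 0.03,
                           dist_ref: float = 0.25) -> PlantedCouplingModel:
    """Per-edge age slopes encode the developmental pattern to be recovered:

        b = age_dist_slope * (dist_ref - D) + age_hierarchy_slope * (0.5 - h_mean)

    The first term makes hierarchically distant edges weaken with age (and
    short edges strengthen); the second makes edges among low-hierarchy
    (sensorimotor-like) networks strengthen and edges among high-hierarchy
    (association-like) networks weaken, so network-level age effects align
    negatively with hierarchy position.  Association-association
    strengthening exists but is damped, as the two terms oppose there.
    """
    h = np.asarray(h_net, dtype=float)
    D = np.abs(h[:, None] - h[None, :])
    h_mean = 0.5 * (h[:, None] + h[None, :])
    b = age_dist_slope * (dist_ref - D) + age_hierarchy_slope * (0.5 - h_mean)
    np.fill_diagonal(b, 0.0)
    return PlantedCouplingModel(h_net=h, intercept=intercept,
                                dist_slope=dist_slope, age_slopes=b)


def repair_correlation(M: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Nearest-in-spirit valid correlation matrix: symmetrize, clip negative
    eigenvalues, renormalize to unit diagonal.  Raises if the result is still
    indefinite beyond ``tol``."""
    if not np.all(np.isfinite(M)):
        raise ValueError("correlation repair failed: non-finite input")
    A = 0.5 * (M + M.T)
    np.fill_diagonal(A, 1.0)
    w, Q = np.linalg.eigh(A)
    if w.min() < 0:
        w = np.clip(w, 1e-10, None)
        A = (Q * w) @ Q.T
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
        np.fill_diagonal(A, 1.0)
    if np.linalg.eigvalsh(A).min() < -tol:
        raise ValueError("correlation repair failed: matrix remains indefinite")
    return A


def planted_coupling_matrix(age: float, model: PlantedCouplingModel,
                            deviation: np.ndarray | None = None) -> np.ndarray:
    """Target network-correlation matrix for a subject of the given age.

    ``deviation`` is an optional symmetric zero-diagonal matrix of
    subject-specific edge offsets (stable individual differences in coupling
    beyond age), which is what cognition models and multivariate prediction
    latch onto after age is controlled."""
    C = (model.intercept - model.dist_slope * model.h_dist
         + model.age_slopes * (age - model.age0))
    if deviation is not None:
        C = C + deviation
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -0.99, 0.99)
    np.fill_diagonal(C, 1.0)
    return repair_correlation(C)


def coupling_deviation(K: int, sd: float, seed: int) -> np.ndarray:
    """Symmetric zero-diagonal Gaussian edge deviations."""
    rng = np.random.default_rng(seed)
    E = np.zeros((K, K))
    iu = np.triu_indices(K, k=1)
    E[iu] = rng.normal(0.0, sd, len(iu[0]))
    return E + E.T


def simulate_timeseries(V_i: np.ndarray, coupling_target: np.ndarray, T: int,
                        noise_sd: float, seed: int) -> np.ndarray:
    """T x S BOLD-like matrix: network courses with the target correlation
    mixed through the subject's loadings plus i.i.d. Gaussian noise."""
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = np.random.default_rng(seed)
    K = V_i.shape[1]
    L = np.linalg.cholesky(repair_correlation(np.asarray(coupling_target, float)))
    courses = rng.standard_normal((T, K)) @ L.T
    X = courses @ V_i.T
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, X.shape)
    return X


def sample_empirical_coupling(coupling_target: np.ndarray, T: int, seed: int) -> np.ndarray:
    """Empirical correlation of T draws from the target — what a finite scan
    measures at the network level."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(repair_correlation(np.asarray(coupling_target, float)))
    draws = rng.standard_normal((T, coupling_target.shape[0])) @ L.T
    return np.corrcoef(draws, rowvar=False)


def ef_edge_weights(h_net: np.ndarray, scale_c: float = 1.0) -> np.ndarray:
    """EF weights over edges encoding the cognition finding to be recovered.

    Each network gets a weight quadratic in its within-scale normalized
    hierarchy position: negative at both extremes (coupling of sensorimotor
    and default-mode analogs is bad for EF — their segregation helps) and
    positive mid-hierarchy (integration of control-like networks helps EF).
    An edge's weight is the mean of its two networks' weights, so
    network-level EF associations inherit the inverted-U shape.
    """
    h = np.asarray(h_net, float)
    rng_h = h.max() - h.min()
    h_tilde = (h - h.min()) / rng_h if rng_h > 0 else np.full_like(h, 0.5)
    omega = scale_c * (1.0 - 8.0 * (h_tilde - 0.5) ** 2)
    w = 0.5 * (omega[:, None] + omega[None, :])
    np.fill_diagonal(w, 0.0)
    return w


def make_ef_scores(cohort: pd.DataFrame,
                   couplings: list[np.ndarray] | dict[int, list[np.ndarray]],
                   weights: np.ndarray | dict[int, np.ndarray],
                   noise_sd: float, seed: int,
                   age_coef: float = 0.08, age0: float = REFERENCE_AGE) -> pd.Series:
    """EF = standardized weighted edge-coupling signal + age trend + noise.

    ``couplings``/``weights`` may be a single scale (list of K x K matrices
    and one weight matrix) or per-scale dicts, in which case the weighted
    sums are pooled over scales."""
    rng = np.random.default_rng(seed)
    if isinstance(couplings, dict):
        pairs = [(couplings[K], weights[K]) for K in sorted(couplings)]
    else:
        pairs = [(couplings, weights)]
    signal = np.zeros(len(cohort))
    for mats, w in pairs:
        iu = np.triu_indices(w.shape[0], k=1)
        signal = signal + np.array([float(C[iu] @ w[iu]) for C in mats])
    sd = signal.std()
    if sd > 0:
        signal = (signal - signal.mean()) / sd
    ef = signal + age_coef * (cohort["age"].to_numpy() - age0)
    if noise_sd > 0:
        ef = ef + rng.normal(0.0, noise_sd, len(ef))
    return pd.Series(ef, index=cohort.index, name="ef")


@dataclass
class GroundTruth:
    """Simulation truth kept aside for recovery tests."""

    hierarchy: np.ndarray
    group_loadings: dict[int, np.ndarray]            # scale -> (S, K)
    subject_loadings: dict[int, list[np.ndarray]]    # scale -> per-subject (S, K)
    coupling_models: dict[int, PlantedCouplingModel]
    coupling_targets: dict[int, list[np.ndarray]]    # scale -> per-subject (K, K)
    ef_weights: dict[int, np.ndarray]                # scale -> (K, K)


@dataclass
class SyntheticConfig:
    """Desk-scale study conditions.

    ``T`` matches the cohort's concatenated scan length (555 volumes); mesh
    subdivision 2 gives 162 vertices, enough to carry contiguous multi-scale
    parcels while staying tractable.
    """

    n_subjects: int = 40
    subdivisions: int = 2
    T: int = 555
    scales: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    topo_sd: float = 0.3
    noise_sd: float = 0.25
    coupling_dev_sd: float = 0.08   # stable subject-specific edge offsets
    ef_noise_sd: float = 1.0
    age_range: tuple[float, float] = (8.0, 23.0)
    hierarchy_noise_sd: float = 0.3
    scale_dependent_topo: bool = False  # optional finer-scale variability boost
    seed: int = 0

    def topo_sd_at(self, K: int) -> float:
        if not self.scale_dependent_topo:
            return self.topo_sd
        k_max = max(self.scales)
        return self.topo_sd * (0.5 + 0.5 * K / k_max)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    mesh: SurfaceMesh
    hierarchy: np.ndarray
    cohort: pd.DataFrame
    truth: GroundTruth
    timeseries: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def generate_dataset(config: SyntheticConfig, with_timeseries: bool = True) -> SyntheticDataset:
    """Full forward simulation at every configured scale.

    Timeseries are generated at the finest configured scale (they contain the
    nested coarser structure through the planted loadings' nesting)."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(6)
    mesh = build_sphere_mesh(config.subdivisions)
    hierarchy = make_hierarchy_map(mesh, int(seeds[0]),
                                   noise_sd=config.hierarchy_noise_sd)
    cohort = make_cohort(config.n_subjects, config.age_range, int(seeds[1]))

    group_loadings: dict[int, np.ndarray] = {}
    subject_loadings: dict[int, list[np.ndarray]] = {}
    coupling_models: dict[int, PlantedCouplingModel] = {}
    coupling_targets: dict[int, list[np.ndarray]] = {}
    per_scale_rng = np.random.SeedSequence(int(seeds[2]))
    scale_seeds = per_scale_rng.generate_state(len(config.scales) * (2 * config.n_subjects + 1))
    si = 0
    for K in config.scales:
        gV = make_group_networks(mesh, K, int(seeds[3]))
        group_loadings[K] = gV
        h_net = network_hierarchy_from_loadings(gV, hierarchy)
        model = planted_coupling_model(h_net)
        coupling_models[K] = model
        subs, targets = [], []
        for i in range(config.n_subjects):
            subs.append(personalize_ground_truth(
                gV, hierarchy, config.topo_sd_at(K), int(scale_seeds[si])))
            dev = coupling_deviation(K, config.coupling_dev_sd,
                                     int(scale_seeds[si + 1]))
            si += 2
            targets.append(planted_coupling_matrix(float(cohort["age"].iloc[i]),
                                                   model, deviation=dev))
        si += 1
        subject_loadings[K] = subs
        coupling_targets[K] = targets

    ref_scale = max(config.scales)
    ef_w = {K: ef_edge_weights(coupling_models[K].h_net) for K in config.scales}
    cohort["ef"] = make_ef_scores(cohort, coupling_targets, ef_w,
                                  config.ef_noise_sd, int(seeds[4]))
    truth = GroundTruth(hierarchy=hierarchy, group_loadings=group_loadings,
                        subject_loadings=subject_loadings,
                        coupling_models=coupling_models,
                        coupling_targets=coupling_targets, ef_weights=ef_w)

    timeseries: dict[str, np.ndarray] = {}
    if with_timeseries:
        ts_seeds = np.random.SeedSequence(int(seeds[5])).generate_state(config.n_subjects)
        for i, sid in enumerate(cohort["subject_id"]):
            timeseries[sid] = simulate_timeseries(
                subject_loadings[ref_scale][i], coupling_targets[ref_scale][i],
                config.T, config.noise_sd, int(ts_seeds[i]))
    return SyntheticDataset(config=config, mesh=mesh, hierarchy=hierarchy,
                            cohort=cohort, truth=truth, timeseries=timeseries)
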