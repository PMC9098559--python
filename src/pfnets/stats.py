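"""Inferential machinery for multi-scale network analyses.

Covers: penalized-spline age/EF models with signed adjusted-R^2 change
effect sizes and derivative-based windows of significant change;
Benjamini-Hochberg FDR; hierarchy-position and hierarchical-distance
regressions with unit-resampling bootstrap; tensor-product interaction
surfaces; estimating-equation (GEE) tests of scale and scale-by-age /
scale-by-EF effects with exchangeable working correlation and sandwich
covariance; spherical spin tests; and the second-order scale-trend
correlation with subject-resampled bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from statsmodels.stats.multitest import multipletests

from .gam import GamFit, anova_f, fit_gam, smooth_basis
from .synthetic import SurfaceMesh

__all__ = [
    "EffectRow",
    "GeeFit",
    "SpinResult",
    "fit_gam",
    "effect_and_significance",
    "derivative_windows",
    "fdr_bh",
    "hierarchy_regression",
    "distance_regression",
    "tensor_surface",
    "fit_gee",
    "gee_scale_test",
    "spin_test",
    "scale_trend",
]


# ---------------------------------------------------------------------------
# effect sizes


@dataclass
class EffectRow:
    unit_id: str
    scale: int
    delta_r2_adj: float
    p_value: float
    fdr_significant: bool = False


def effect_and_significance(full: GamFit, reduced: GamFit,
                            linear_sign: float) -> tuple[float, float]:
    """Signed effect size and p for the term dropped between two nested fits.

    Effect = |R^2_adj(full) - R^2_adj(reduced)| signed by the equivalent
    linear model's coefficient; p from an F comparison on effective df.
    """
    delta = full.adj_r2 - reduced.adj_r2
    signed = float(np.sign(linear_sign) if linear_sign != 0 else 1.0) * abs(delta)
    return signed, anova_f(full, reduced)


def linear_coefficient(y: np.ndarray, x: np.ndarray,
                       covariates: dict[str, np.ndarray] | None = None) -> float:
    """Coefficient of x in the equivalent linear model (sign source)."""
    cols = [np.ones_like(x), np.asarray(x, float)]
    if covariates:
        cols += [np.asarray(c, float) for c in covariates.values()]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, np.asarray(y, float), rcond=None)
    return float(beta[1])


def age_effect(y: np.ndarray, age: np.ndarray, sex: np.ndarray,
               motion: np.ndarray, df: int = 8) -> tuple[float, float, GamFit]:
    """Convenience wrapper: FC ~ s(age) + sex + motion versus the nested
    model without age; returns (signed delta R2_adj, p, full fit)."""
    cov = {"sex": sex, "motion": motion}
    full = fit_gam(y, cov, {"age": age}, df=df)
    red = fit_gam(y, cov, {}, df=df)
    sign = linear_coefficient(y, age, cov)
    d, p = effect_and_significance(full, red, sign)
    return d, p, full


def ef_effect(y: np.ndarray, ef: np.ndarray, age: np.ndarray, sex: np.ndarray,
              motion: np.ndarray, df: int = 8) -> tuple[float, float, GamFit]:
    """FC ~ s(EF) + s(age) + sex + motion versus the model without EF."""
    cov = {"sex": sex, "motion": motion}
    full = fit_gam(y, cov, {"ef": ef, "age": age}, df=df)
    red = fit_gam(y, cov, {"age": age}, df=df)
    sign = linear_coefficient(y, ef, {"age": age, **cov})
    d, p = effect_and_significance(full, red, sign)
    return d, p, full


def derivative_windows(fit: GamFit, term: str, grid: np.ndarray,
                       level: float = 0.95, n_sim: int = 1000,
                       seed: int = 0) -> list[tuple[float, float, int]]:
    """Contiguous grid intervals where the pointwise simulation CI of the
    smooth's first derivative excludes zero; sign is +1/-1 per window."""
    point, draws = fit.smooth_derivative_draws(term, grid, n_sim, seed)
    alpha = (1 - level) / 2
    lo = np.percentile(draws, 100 * alpha, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha), axis=0)
    sig = np.where(lo > 0, 1, np.where(hi < 0, -1, 0))
    windows: list[tuple[float, float, int]] = []
    start, cur = None, 0
    for i, s in enumerate(sig):
        if s != cur:
            if cur != 0 and start is not None:
                windows.append((float(grid[start]), float(grid[i - 1]), int(cur)))
            start = i if s != 0 else None
            cur = int(s)
    if cur != 0 and start is not None:
        windows.append((float(grid[start]), float(grid[-1]), int(cur)))
    return windows


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags."""
    p = np.asarray(p_values, float)
    flags = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


# ---------------------------------------------------------------------------
# second-order (hierarchy) regressions


def _boot_ci(stat_fn: Callable[[np.ndarray], np.ndarray], n_units: int,
             n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_units, n_units)
        draws.append(stat_fn(idx))
    return np.asarray(draws)


def hierarchy_regression(effects: np.ndarray, h_values: np.ndarray,
                         quadratic: bool = False, n_boot: int = 1000,
                         seed: int = 0) -> dict:
    """OLS of unit effects on hierarchy position (optionally + squared term)
    with unit-resampling bootstrap CIs and a Spearman correlation."""
    y = np.asarray(effects, float)
    h = np.asarray(h_values, float)
    ok = np.isfinite(y) & np.isfinite(h)
    y, h = y[ok], h[ok]

    def coefs(idx):
        hh, yy = h[idx], y[idx]
        cols = [np.ones_like(hh), hh] + ([hh ** 2] if quadratic else [])
        beta, *_ = np.linalg.lstsq(np.column_stack(cols), yy, rcond=None)
        return beta

    beta = coefs(np.arange(len(y)))
    draws = _boot_ci(coefs, len(y), n_boot, seed)
    ci = np.percentile(draws, [2.5, 97.5], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sps.spearmanr(h, y).statistic if len(y) > 2 else np.nan
        pearson = sps.pearsonr(h, y).statistic if len(y) > 2 else np.nan
    out = {
        "intercept": float(beta[0]),
        "slope": float(beta[1]),
        "slope_ci": (float(ci[0, 1]), float(ci[1, 1])),
        "spearman_r": float(rho),
        "pearson_r": float(pearson),
        "n_units": int(len(y)),
    }
    if quadratic:
        out["quadratic"] = float(beta[2])
        out["quadratic_ci"] = (float(ci[0, 2]), float(ci[1, 2]))
    return out


def distance_regression(edge_effects: np.ndarray, h_dist: np.ndarray,
                        euclid_dist: np.ndarray | None = None,
                        n_boot: int = 1000, seed: int = 0) -> dict:
    """Edge effects regressed on hierarchical distance, with bootstrap CI;
    partial correlation controls Euclidean distance when supplied."""
    y = np.asarray(edge_effects, float)
    d = np.asarray(h_dist, float)
    ok = np.isfinite(y) & np.isfinite(d)
    if euclid_dist is not None:
        e = np.asarray(euclid_dist, float)
        ok &= np.isfinite(e)
        e = e[ok]
    y, d = y[ok], d[ok]

    def slope(idx):
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(idx)), d[idx]]), y[idx], rcond=None)
        return beta[1:2]

    if len(y) < 3:
        return {"slope": np.nan, "slope_ci": (np.nan, np.nan),
                "pearson_r": np.nan, "n_units": int(len(y))}
    beta1 = float(slope(np.arange(len(y)))[0])
    draws = _boot_ci(slope, len(y), n_boot, seed)
    ci = np.percentile(draws[:, 0], [2.5, 97.5])
    out = {
        "slope": beta1,
        "slope_ci": (float(ci[0]), float(ci[1])),
        "pearson_r": float(sps.pearsonr(d, y).statistic),
        "n_units": int(len(y)),
    }
    if euclid_dist is not None:
        def resid(a, b):
            X = np.column_stack([np.ones(len(b)), b])
            beta, *_ = np.linalg.lstsq(X, a, rcond=None)
            return a - X @ beta
        ry = resid(y, e)
        rd = resid(d, e)
        out["partial_r"] = float(sps.pearsonr(rd, ry).statistic)
        out["euclid_r"] = float(sps.pearsonr(e, y).statistic)
    return out


def tensor_surface(edge_effects: np.ndarray, h_a: np.ndarray, h_b: np.ndarray,
                   n_boot: int = 1000, seed: int = 0, df: int = 5,
                   grid_size: int = 25) -> dict:
    """Bivariate penalized surface of edge effects over the two networks'
    hierarchy positions (visualization), with inference from a bootstrap of
    the linear product-interaction model."""
    y = np.asarray(edge_effects, float)
    a = np.asarray(h_a, float)
    b = np.asarray(h_b, float)
    ok = np.isfinite(y) & np.isfinite(a) & np.isfinite(b)
    y, a, b = y[ok], a[ok], b[ok]

    # --- penalized tensor-product smooth (single shared lambda) ---
    ta = smooth_basis(a, "ha", df=df)
    tb = smooth_basis(b, "hb", df=df)
    Ba, Bb = ta.raw_basis(a), tb.raw_basis(b)
    n, pa = Ba.shape
    pb = Bb.shape[1]
    BT = np.einsum("ni,nj->nij", Ba, Bb).reshape(n, pa * pb)
    Da = np.diff(np.eye(pa), n=2, axis=0)
    Db = np.diff(np.eye(pb), n=2, axis=0)
    S = np.kron(Da.T @ Da, np.eye(pb)) + np.kron(np.eye(pa), Db.T @ Db)

    def gcv(log_lam):
        lam = np.exp(log_lam)
        A = BT.T @ BT + lam * S + 1e-10 * np.eye(pa * pb)
        H = BT @ np.linalg.solve(A, BT.T)
        tr = np.trace(H)
        r = y - H @ y
        return n * (r @ r) / max(n - tr, 1.0) ** 2

    grid = np.linspace(-6, 12, 10)
    lam = float(np.exp(grid[int(np.argmin([gcv(g) for g in grid]))]))
    A = BT.T @ BT + lam * S + 1e-10 * np.eye(pa * pb)
    coef = np.linalg.solve(A, BT.T @ y)
    ga = np.linspace(a.min(), a.max(), grid_size)
    gb = np.linspace(b.min(), b.max(), grid_size)
    Ga, Gb = ta.raw_basis(ga), tb.raw_basis(gb)
    surface = np.einsum("ik,jl,kl->ij", Ga, Gb, coef.reshape(pa, pb))

    # --- linear interaction bootstrap ---
    def inter(idx):
        aa, bb, yy = a[idx], b[idx], y[idx]
        X = np.column_stack([np.ones(len(idx)), aa, bb, aa * bb])
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        return beta[3:4]

    beta_int = float(inter(np.arange(n))[0])
    draws = _boot_ci(inter, n, n_boot, seed)
    ci = np.percentile(draws[:, 0], [2.5, 97.5])
    return {
        "surface": surface, "grid_a": ga, "grid_b": gb, "lambda": lam,
        "interaction": beta_int,
        "interaction_ci": (float(ci[0]), float(ci[1])),
    }


# ---------------------------------------------------------------------------
# GEE across scales


@dataclass
class GeeFit:
    params: np.ndarray
    cov: np.ndarray
    dep_params: float
    wald_stat: float
    wald_p: float
    wald_df: int
    column_names: list[str]


def fit_gee(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
            tested_cols: Sequence[int],
            column_names: list[str] | None = None,
            start_params: np.ndarray | None = None) -> GeeFit:
    """GEE with exchangeable working correlation and robust (sandwich)
    covariance; joint Wald chi-square on ``tested_cols``.

    Smooth terms should arrive pre-expanded into fixed basis columns (the
    basis frozen from the additive-model stage).  With one observation per
    cluster the fit degrades to independence (robust OLS) with a warning.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    _, counts = np.unique(groups, return_counts=True)
    if counts.max() == 1:
        warnings.warn("single observation per cluster; GEE reduces to robust OLS")
        cov_struct = sm.cov_struct.Independence()
    else:
        cov_struct = sm.cov_struct.Exchangeable()
    model = sm.GEE(y, X, groups=groups, cov_struct=cov_struct,
                   family=sm.families.Gaussian())
    res = model.fit(start_params=start_params, maxiter=100)
    tested = np.asarray(tested_cols, dtype=int)
    R = np.zeros((len(tested), X.shape[1]))
    R[np.arange(len(tested)), tested] = 1.0
    wt = res.wald_test(R, scalar=True)
    dep = getattr(res.cov_struct, "dep_params", None)
    if dep is None:
        dep = 0.0
    return GeeFit(params=np.asarray(res.params), cov=np.asarray(res.cov_params()),
                  dep_params=float(np.atleast_1d(dep)[0]),
                  wald_stat=float(wt.statistic), wald_p=float(wt.pvalue),
                  wald_df=len(tested),
                  column_names=column_names or [f"x{i}" for i in range(X.shape[1])])


def _reduce_rank(Z: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Drop redundant directions (few unique covariate values make spline
    bases rank deficient); keeps an orthonormal column basis."""
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    keep = s > tol * s[0]
    return U[:, keep] * s[keep]


def _expanded_design(long: pd.DataFrame, smooth_cols: Sequence[str],
                     linear_cols: Sequence[str], df: int,
                     interactions: Sequence[tuple[str, str]] = ()) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Intercept + linear covariates + centered spline bases per smooth
    column (+ optional product-interaction blocks of two spline bases)."""
    n = len(long)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    slices: dict[str, slice] = {}
    pos = 1
    for c in linear_cols:
        blocks.append(long[c].to_numpy(float).reshape(n, 1))
        names.append(c)
        pos += 1
    bases = {}
    for c in smooth_cols:
        term = smooth_basis(long[c].to_numpy(float), name=c, df=df)
        Z = _reduce_rank(term.design(long[c].to_numpy(float)))
        bases[c] = (term, Z)
        blocks.append(Z)
        slices[f"s({c})"] = slice(pos, pos + Z.shape[1])
        names += [f"s({c}).{j}" for j in range(Z.shape[1])]
        pos += Z.shape[1]
    for ca, cb in interactions:
        Za = bases[ca][1]
        Zb = bases[cb][1]
        # low-rank product interaction: elementwise products of the two
        # leading basis directions keeps the Wald block small
        ka = min(2, Za.shape[1])
        kb = min(2, Zb.shape[1])
        ZI = _reduce_rank(np.concatenate(
            [(Za[:, i] * Zb[:, j]).reshape(n, 1)
             for i in range(ka) for j in range(kb)], axis=1))
        blocks.append(ZI)
        slices[f"ti({ca},{cb})"] = slice(pos, pos + ZI.shape[1])
        names += [f"ti({ca},{cb}).{j}" for j in range(ZI.shape[1])]
        pos += ZI.shape[1]
    return np.hstack(blocks), names, slices


def gee_scale_test(long: pd.DataFrame, response: str = "coupling",
                   cluster: str = "subject_id", df: int = 5,
                   interaction_with: str | None = None) -> GeeFit:
    """Across-scale inference at one unit (e.g., a vertex).

    Without ``interaction_with``: response ~ s(scale) + sex + motion, joint
    Wald on the scale-smooth block.  With it (e.g., "age" or "ef"):
    response ~ s(scale) + s(other) + ti(scale, other) + sex + motion, joint
    Wald on the tensor-interaction block.
    """
    smooth_cols = ["scale"] + ([interaction_with] if interaction_with else [])
    inter = [("scale", interaction_with)] if interaction_with else ()
    X, names, slices = _expanded_design(long, smooth_cols,
                                        ["sex", "motion"], df, inter)
    if interaction_with:
        tested = range(*slices[f"ti(scale,{interaction_with})"].indices(X.shape[1]))
    else:
        tested = range(*slices["s(scale)"].indices(X.shape[1]))
    # initialize at the independence (penalizer-free additive) estimates
    beta0, *_ = np.linalg.lstsq(X, long[response].to_numpy(float), rcond=None)
    return fit_gee(long[response].to_numpy(float), X,
                   long[cluster].to_numpy(), list(tested), names,
                   start_params=beta0)


# ---------------------------------------------------------------------------
# spin test


@dataclass
class SpinResult:
    observed: float
    nulls: np.ndarray
    p_value: float

    @property
    def n_rot(self) -> int:
        return len(self.nulls)


def spin_test(map_a: np.ndarray, map_b: np.ndarray, mesh: SurfaceMesh,
              n_rot: int = 1000, seed: int = 0) -> SpinResult:
    """Spherical spatial permutation: map_a is resampled under uniformly
    random 3D rotations (nearest-vertex), preserving its spatial
    autocorrelation; two-sided add-one p on |Pearson r|."""
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_rot, random_state=rng)
    tree = cKDTree(mesh.coords)
    nulls = np.empty(n_rot)
    for i in range(n_rot):
        rotated = mesh.coords @ rots[i].as_matrix().T
        _, idx = tree.query(rotated)
        nulls[i] = np.corrcoef(a[idx], b)[0, 1]
    p = (1.0 + np.sum(np.abs(nulls) >= abs(obs))) / (n_rot + 1.0)
    return SpinResult(observed=obs, nulls=nulls, p_value=float(p))


# ---------------------------------------------------------------------------
# scale trend


def scale_trend(scales: Sequence[int], per_scale_stats: Sequence[float],
                n_boot: int = 1000, seed: int = 0,
                stat_fn: Callable[[np.ndarray], np.ndarray] | None = None,
                n_subjects: int | None = None) -> dict:
    """Second-order Pearson correlation between scale and a per-scale
    statistic.  When ``stat_fn`` (subject index array -> per-scale stats) and
    ``n_subjects`` are given, the CI comes from subject-resampled bootstrap
    recomputation; constant stats yield a flagged zero."""
    k = np.asarray(scales, float)
    s = np.asarray(per_scale_stats, float)
    if np.std(s) == 0 or np.std(k) == 0:
        return {"r": 0.0, "ci": None, "degenerate": True}
    r = float(np.corrcoef(k, s)[0, 1])
    ci = None
    if stat_fn is not None and n_subjects is not None:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, n_subjects, n_subjects)
            sb = np.asarray(stat_fn(idx), float)
            draws.append(np.corrcoef(k, sb)[0, 1] if np.std(sb) > 0 else 0.0)
        ci = tuple(np.percentile(draws, [2.5, 97.5]))
    return {"r": r, "ci": ci, "degenerate": False}
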