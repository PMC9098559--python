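"""Penalized-spline additive models for Gaussian responses.

A small, self-contained engine in the style of classical additive-model
software: each smooth term is a cubic B-spline basis with a second-difference
penalty (the discrete analog of an integrated-squared-second-derivative
penalty), sum-to-zero constrained so it is identifiable next to a global
intercept.  Parametric covariates are unpenalized.  The smoothing parameter
of every term is chosen by minimizing the (Gaussian, profiled-variance)
restricted marginal likelihood, so nonlinearity is penalized rather than
chosen by basis dimension.

The fitted object exposes what downstream inference needs: effective degrees
of freedom, adjusted R^2, a coefficient posterior (for derivative
simulation), and frozen term bases for estimating-equation re-fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats
from scipy.interpolate import BSpline

__all__ = ["SmoothTerm", "GamFit", "fit_gam", "smooth_basis"]


@dataclass
class SmoothTerm:
    """A constrained B-spline smooth of one covariate."""

    name: str
    knots: np.ndarray
    degree: int
    constraint: np.ndarray      # (n_basis, n_basis-1) sum-to-zero projector
    penalty: np.ndarray         # constrained penalty matrix
    penalty_rank: int
    x_min: float
    x_max: float

    def raw_basis(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, float), self.x_min, self.x_max)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def design(self, x: np.ndarray) -> np.ndarray:
        return self.raw_basis(x) @ self.constraint


def smooth_basis(x: np.ndarray, name: str = "s", df: int = 8,
                 degree: int = 3) -> SmoothTerm:
    """Build a smooth term from observed covariate values.

    ``df`` is the unconstrained basis dimension; interior knots sit at
    quantiles of ``x``.
    """
    x = np.asarray(x, float)
    x_min, x_max = float(x.min()), float(x.max())
    if x_max <= x_min:
        raise ValueError(f"covariate {name!r} is constant")
    n_interior = df - degree - 1
    if n_interior < 0:
        raise ValueError("df too small for the spline degree")
    # uniform unclamped (P-spline) knots extending past the boundary: the
    # second-difference penalty's null space is then exactly the linear
    # functions, so the lambda -> inf limit of the smooth is a straight line
    h = (x_max - x_min) / (n_interior + 1)
    knots = x_min + h * np.arange(-degree, n_interior + 2 + degree)
    knots[degree] = x_min          # pin the boundary knots exactly so that
    knots[-degree - 1] = x_max     # clipped data stay inside the domain
    n_basis = len(knots) - degree - 1
    # second-difference penalty on raw coefficients
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    S_raw = D.T @ D
    # sum-to-zero constraint over the observed sample: 1'B c = 0
    # build column-sum constraint and project onto its null space
    term = SmoothTerm(name=name, knots=knots, degree=degree,
                      constraint=np.eye(n_basis), penalty=S_raw,
                      penalty_rank=n_basis - 2, x_min=x_min, x_max=x_max)
    B = term.raw_basis(x)
    c = B.sum(axis=0, keepdims=True)
    _, _, Vt = np.linalg.svd(c, full_matrices=True)
    Z = Vt[1:].T                                   # (n_basis, n_basis-1)
    term.constraint = Z
    term.penalty = Z.T @ S_raw @ Z
    term.penalty_rank = int(np.linalg.matrix_rank(S_raw))  # = n_basis - 2
    return term


@dataclass
class GamFit:
    """Penalized-least-squares fit with REML-chosen smoothing parameters."""

    coef: np.ndarray
    cov: np.ndarray                 # posterior covariance sigma^2 (X'X + S)^-1
    sigma2: float
    fitted: np.ndarray
    residuals: np.ndarray
    edf_total: float
    edf_terms: dict[str, float]
    adj_r2: float
    rss: float
    lambdas: dict[str, float]
    terms: dict[str, SmoothTerm]
    term_slices: dict[str, slice]
    n_par: int                      # parametric columns incl. intercept
    column_names: list[str]
    n_obs: int

    def smooth_values(self, name: str, x: np.ndarray) -> np.ndarray:
        Z = self.terms[name].design(x)
        return Z @ self.coef[self.term_slices[name]]

    def smooth_derivative_draws(self, name: str, x: np.ndarray, n_sim: int,
                                seed: int, eps: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Finite-difference derivative of the smooth on a grid plus draws
        from the coefficient posterior; returns (point_estimate, draws)."""
        term = self.terms[name]
        if eps is None:
            eps = 1e-4 * (term.x_max - term.x_min)
        Zp = term.design(np.asarray(x) + eps)
        Zm = term.design(np.asarray(x) - eps)
        Dmat = (Zp - Zm) / (2 * eps)
        sl = self.term_slices[name]
        point = Dmat @ self.coef[sl]
        rng = np.random.default_rng(seed)
        block_cov = self.cov[sl, sl]
        draws_coef = rng.multivariate_normal(self.coef[sl], block_cov,
                                             size=n_sim, method="svd")
        return point, draws_coef @ Dmat.T


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        bad = np.abs(vt[rank:]).max(axis=0) > 1e-8
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"design is rank deficient; collinear columns: {cols}")


def fit_gam(y: np.ndarray,
            covariates: dict[str, np.ndarray] | None,
            smooth_terms: dict[str, np.ndarray],
            df: int = 8,
            lambda_bounds: tuple[float, float] = (-8.0, 16.0)) -> GamFit:
    """Additive Gaussian model: intercept + parametric covariates + one
    penalized smooth per entry of ``smooth_terms`` (name -> covariate).

    Smoothing parameters minimize the profiled restricted marginal
    likelihood; with the second-difference penalty the infinite-penalty
    limit of each smooth is a straight line.
    """
    y = np.asarray(y, float)
    n = y.shape[0]
    covariates = covariates or {}
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for cname, col in covariates.items():
        blocks.append(np.asarray(col, float).reshape(n, 1))
        names.append(cname)
    n_par = len(names)

    terms: dict[str, SmoothTerm] = {}
    term_slices: dict[str, slice] = {}
    pos = n_par
    for sname, x in smooth_terms.items():
        term = smooth_basis(np.asarray(x, float), name=sname, df=df)
        Z = term.design(np.asarray(x, float))
        terms[sname] = term
        term_slices[sname] = slice(pos, pos + Z.shape[1])
        blocks.append(Z)
        names.extend([f"{sname}.{j}" for j in range(Z.shape[1])])
        pos += Z.shape[1]
    X = np.hstack(blocks)
    _check_rank(X, names)
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    S_blocks = {name: terms[name].penalty for name in terms}
    rank_pen = sum(terms[t].penalty_rank for t in terms)
    Mp = p - rank_pen  # unpenalized dimension

    def assemble(lams: np.ndarray) -> np.ndarray:
        S = np.zeros((p, p))
        for lam, name in zip(lams, terms):
            sl = term_slices[name]
            S[sl, sl] += lam * S_blocks[name]
        return S

    def reml(log_lams: np.ndarray) -> float:
        lams = np.exp(np.clip(log_lams, lambda_bounds[0] - 2, lambda_bounds[1] + 2))
        S = assemble(lams)
        A = XtX + S
        try:
            cf = np.linalg.cholesky(A + 1e-10 * np.eye(p))
            coef = linalg.cho_solve((cf, True), Xty)
        except np.linalg.LinAlgError:  # pragma: no cover
            return np.inf
        rss = yty - 2 * coef @ Xty + coef @ XtX @ coef
        pen = float(coef @ S @ coef)
        sigma2 = max((rss + pen) / max(n - Mp, 1), 1e-300)
        logdet_A = 2 * np.sum(np.log(np.diag(cf)))
        logdet_S = 0.0
        for lam, name in zip(lams, terms):
            r = terms[name].penalty_rank
            w = np.linalg.eigvalsh(S_blocks[name])
            w = w[w > 1e-10 * w.max()]
            logdet_S += r * np.log(lam) + float(np.sum(np.log(w)))
        return 0.5 * ((n - Mp) * (np.log(2 * np.pi * sigma2) + 1)
                      + logdet_A - logdet_S - Mp * np.log(sigma2))

    lambdas: dict[str, float] = {}
    if terms:
        n_terms = len(terms)
        grid = np.linspace(lambda_bounds[0], lambda_bounds[1], 13)
        if n_terms == 1:
            vals = [reml(np.array([g])) for g in grid]
            g0 = grid[int(np.argmin(vals))]
            res = optimize.minimize_scalar(
                lambda g: reml(np.array([g])),
                bounds=(max(g0 - 2.5, lambda_bounds[0]), min(g0 + 2.5, lambda_bounds[1])),
                method="bounded")
            best = np.array([res.x])
        else:
            coarse = np.linspace(lambda_bounds[0], lambda_bounds[1], 7)
            best, best_val = None, np.inf
            mesh = np.meshgrid(*([coarse] * n_terms), indexing="ij")
            pts = np.stack([m.ravel() for m in mesh], axis=1)
            for pt in pts:
                v = reml(pt)
                if v < best_val:
                    best, best_val = pt, v
            res = optimize.minimize(reml, best, method="Nelder-Mead",
                                    options={"xatol": 1e-3, "fatol": 1e-6,
                                             "maxiter": 300})
            best = np.clip(res.x, *lambda_bounds)
        lambdas = {name: float(np.exp(b)) for name, b in zip(terms, best)}

    S = assemble(np.array([lambdas[t] for t in terms])) if terms else np.zeros((p, p))
    A = XtX + S
    coef = np.linalg.solve(A, Xty)
    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    Ainv = np.linalg.inv(A)
    H_diag_like = Ainv @ XtX
    edf_total = float(np.trace(H_diag_like))
    edf_terms = {}
    for name in terms:
        sl = term_slices[name]
        edf_terms[name] = float(np.trace(H_diag_like[sl, sl]))
    sigma2 = rss / max(n - edf_total, 1.0)
    ssy = float(np.sum((y - y.mean()) ** 2))
    adj_r2 = 1.0 - (rss / max(n - edf_total, 1e-12)) / (ssy / (n - 1)) if ssy > 0 else 0.0
    return GamFit(coef=coef, cov=sigma2 * Ainv, sigma2=sigma2, fitted=fitted,
                  residuals=resid, edf_total=edf_total, edf_terms=edf_terms,
                  adj_r2=adj_r2, rss=rss, lambdas=lambdas, terms=terms,
                  term_slices=term_slices, n_par=n_par, column_names=names,
                  n_obs=n)


def anova_f(full: GamFit, reduced: GamFit) -> float:
    """F-comparison of two nested penalized fits on effective df."""
    df1 = max(full.edf_total - reduced.edf_total, 1e-8)
    df2 = max(full.n_obs - full.edf_total, 1.0)
    num = max(reduced.rss - full.rss, 0.0) / df1
    den = full.rss / df2
    if den <= 0:
        return 0.0 if num <= 0 else np.inf
    F = num / den
    return float(stats.f.sf(F, df1, df2))
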