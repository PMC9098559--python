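"""Multivariate ridge prediction of executive function from multi-scale
edge couplings.

The estimator follows a nested split-thirds protocol: per repeat the cohort
is randomly split into three folds; ridge coefficients are fit on the first
third across a penalty grid, the penalty is chosen by mean-squared error on
the second third, and performance is measured only on the untouched final
third.  Covariates (age, motion) are residualized out of the response using
a projection estimated on the two training thirds; feature standardization
uses the fitting third alone.  Per-subject predictions are averaged across
the repeats in which the subject fell in the evaluation third, and summary
r / MSE are computed on those averaged predictions.  Significance comes
from re-running the whole procedure on permuted responses.

Ridge solves use an SVD of the standardized fitting matrix so the entire
penalty grid is evaluated in one decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PredictionResult",
    "assemble_feature_matrix",
    "ridge_nested_predict",
    "permutation_test",
    "default_lambda_grid",
]


@dataclass
class PredictionResult:
    predictions: np.ndarray        # per-subject averaged out-of-sample prediction
    actual: np.ndarray
    r: float
    mse: float
    chosen_lambdas: np.ndarray     # per repeat
    per_repeat_r: np.ndarray
    n_repeats: int
    constant_flagged: bool = False


def assemble_feature_matrix(edge_matrices: dict[int, list[np.ndarray]],
                            scales: list[int] | tuple[int, ...]
                            ) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Subjects x features matrix of vectorized upper-triangle between-network
    couplings concatenated over scales (ascending scale, then row-major
    upper-triangle order).  Missing edges are column-mean imputed.

    Returns the matrix and the (scale, netA, netB) label of every column.
    """
    cols, labels = [], []
    n_subj = len(edge_matrices[scales[0]])
    for K in sorted(scales):
        mats = edge_matrices[K]
        if len(mats) != n_subj:
            raise ValueError("inconsistent subject counts across scales")
        iu = np.triu_indices(K, k=1)
        block = np.stack([m[iu] for m in mats])   # (n_subj, K(K-1)/2)
        cols.append(block)
        labels += [(K, int(a), int(b)) for a, b in zip(*iu)]
    X = np.hstack(cols)
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
    return X, labels


def default_lambda_grid(X: np.ndarray, n: int = 20) -> np.ndarray:
    """Log-spaced grid spanning 1e-3 to 1e4 times the mean feature variance."""
    v = float(np.mean(np.var(X, axis=0)))
    v = v if v > 0 else 1.0
    return v * np.logspace(-3, 4, n)


def _ridge_grid_coefs(Xtr: np.ndarray, ytr: np.ndarray,
                      lambdas: np.ndarray) -> np.ndarray:
    """Ridge coefficients for every lambda from one SVD. Returns (L, p)."""
    U, s, Vt = np.linalg.svd(Xtr, full_matrices=False)
    Uty = U.T @ ytr
    # coef = V diag(s/(s^2+lam)) U'y
    factors = s[None, :] / (s[None, :] ** 2 + lambdas[:, None])
    return (factors * Uty[None, :]) @ Vt


def _one_repeat(X: np.ndarray, y: np.ndarray, C: np.ndarray | None,
                lambdas: np.ndarray, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """One three-way split; returns (eval indices, eval predictions, lambda)."""
    n = len(y)
    perm = rng.permutation(n)
    third = n // 3
    f1, f2, f3 = perm[:third], perm[third:2 * third], perm[2 * third:]
    train = np.concatenate([f1, f2])
    if C is not None:
        Xc = np.column_stack([np.ones(n), C])
        beta, *_ = np.linalg.lstsq(Xc[train], y[train], rcond=None)
        y_use = y - Xc @ beta
    else:
        y_use = y
    mu = X[f1].mean(axis=0)
    sd = X[f1].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z1 = (X[f1] - mu) / sd
    Z2 = (X[f2] - mu) / sd
    Z3 = (X[f3] - mu) / sd
    y1_mean = y_use[f1].mean()
    coefs = _ridge_grid_coefs(Z1, y_use[f1] - y1_mean, lambdas)   # (L, p)
    pred2 = Z2 @ coefs.T + y1_mean                                 # (n2, L)
    mse2 = np.mean((pred2 - y_use[f2][:, None]) ** 2, axis=0)
    best = int(np.argmin(mse2))
    pred3 = Z3 @ coefs[best] + y1_mean
    return f3, pred3, float(lambdas[best])


def ridge_nested_predict(features: np.ndarray, y: np.ndarray,
                         covariates: np.ndarray | None = None,
                         lambda_grid: np.ndarray | None = None,
                         n_repeats: int = 100, seed: int = 0,
                         allow_partial: bool = False) -> PredictionResult:
    """Nested split-thirds ridge with repeat-averaged predictions.

    ``allow_partial`` computes the summary over subjects that entered at
    least one evaluation third instead of erroring (used by the permutation
    null, where few repeats per permutation are the norm)."""
    X = np.asarray(features, float)
    y = np.asarray(y, float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X)
    lambda_grid = np.asarray(lambda_grid, float)
    if lambda_grid.size == 0 or np.any(lambda_grid <= 0):
        raise ValueError("lambda grid must be nonempty and positive")
    rng = np.random.default_rng(seed)
    n = len(y)
    sums = np.zeros(n)
    counts = np.zeros(n)
    chosen = np.empty(n_repeats)
    rep_r = np.empty(n_repeats)
    tol = 1e-9 * (y.std() + 1e-300)
    n_constant_reps = 0
    for rep in range(n_repeats):
        f3, pred3, lam = _one_repeat(X, y, covariates, lambda_grid, rng)
        sums[f3] += pred3
        counts[f3] += 1
        chosen[rep] = lam
        sd = pred3.std()
        n_constant_reps += sd <= tol
        rep_r[rep] = np.corrcoef(pred3, y[f3])[0, 1] if sd > tol else 0.0
    covered = counts > 0
    if not covered.all():
        if not allow_partial:
            raise RuntimeError("some subjects never entered an evaluation third; "
                               "increase n_repeats")
    pred = np.full(n, np.nan)
    pred[covered] = sums[covered] / counts[covered]
    # effectively constant predictions (e.g. the infinite-shrinkage limit,
    # where every repeat predicts its training mean) leave r undefined;
    # it is reported as a flagged 0
    flagged = (n_constant_reps == n_repeats
               or pred[covered].std() <= 1e-9 * (y.std() + 1e-300))
    r = 0.0 if flagged else float(np.corrcoef(pred[covered], y[covered])[0, 1])
    mse = float(np.mean((pred[covered] - y[covered]) ** 2))
    return PredictionResult(predictions=pred, actual=y.copy(), r=r, mse=mse,
                            chosen_lambdas=chosen, per_repeat_r=rep_r,
                            n_repeats=n_repeats, constant_flagged=bool(flagged))


def permutation_test(features: np.ndarray, y: np.ndarray,
                     covariates: np.ndarray | None = None,
                     lambda_grid: np.ndarray | None = None,
                     n_repeats: int = 20, n_perm: int = 200,
                     seed: int = 0) -> dict:
    """One-sided permutation p for the observed prediction correlation:
    the full nested procedure re-runs on each permuted response."""
    rng = np.random.default_rng(seed)
    obs = ridge_nested_predict(features, y, covariates, lambda_grid,
                               n_repeats=n_repeats, allow_partial=True,
                               seed=int(rng.integers(2**31 - 1)))
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        res = ridge_nested_predict(features, yp, covariates, lambda_grid,
                                   n_repeats=n_repeats, allow_partial=True,
                                   seed=int(rng.integers(2**31 - 1)))
        nulls[i] = res.r
    p = (1.0 + np.sum(nulls >= obs.r)) / (n_perm + 1.0)
    return {"observed_r": obs.r, "observed_mse": obs.mse, "nulls": nulls,
            "p_value": float(p), "result": obs}
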