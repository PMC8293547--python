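"""Multicollinearity diagnostics and penalized regression.

The elastic net minimizes

    (1/2N) sum_i (y_i - b0 - x_i' b)^2 + lambda * P_alpha(b),
    P_alpha(b) = (1 - alpha) * 0.5 * ||b||_2^2 + alpha * ||b||_1,

fit by cyclic coordinate descent with soft-thresholding. alpha = 1 is the
lasso, alpha = 0 ridge. The penalty parameter lambda is chosen by k-fold
cross-validation minimizing held-out mean squared error, and the final
coefficients are refit on all data at the selected lambda.

Collinearity screening reports, per predictor, the tolerance (1 - R^2 of
that column regressed on the others) and its reciprocal, the variance
inflation factor (VIF); tolerance < 0.1 or VIF > 10 flags strict
multicollinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "EnetSolution",
    "RegularizedFit",
    "SupportOverlap",
    "standardize",
    "vif",
    "enet_objective",
    "fit_enet",
    "lambda_path",
    "cross_validate",
    "compare_supports",
    "kkt_residual",
]

VIF_FLAG_THRESHOLD = 10.0
TOLERANCE_FLAG_THRESHOLD = 0.1

#: alpha = 0 has no finite lambda zeroing all coefficients; the path top is
#: computed with this surrogate mixing value instead (glmnet convention).
RIDGE_LAMBDA_MAX_SURROGATE = 1e-3


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class DesignMatrix:
    """Standardized design: centered/scaled X, centered y, and the stats
    needed to express coefficients back on the original scale."""

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def standardize(X, y, column_names: Sequence[str] | None = None) -> DesignMatrix:
    """Center X's columns to mean 0 and scale to sample sd 1 (denominator n);
    center y. Zero-variance columns are dropped with a warning."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"X {X.shape} and y {y.shape} do not conform")
    if X.shape[0] < 2:
        raise ValueError("standardize requires at least 2 rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite with no missing values")
    names = list(column_names) if column_names is not None else [
        f"X{j + 1}" for j in range(X.shape[1])]
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0: n-denominator
    keep = sd > 0
    dropped = [names[j] for j in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return DesignMatrix(X=Xs, y=y - y.mean(),
                        column_names=[names[j] for j in np.flatnonzero(keep)],
                        x_mean=mean[keep], x_sd=sd[keep], y_mean=float(y.mean()),
                        dropped_columns=dropped)


# ---------------------------------------------------------------------------
# collinearity diagnostics
# ---------------------------------------------------------------------------

def vif(X, column_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Tolerance and VIF per column from exact OLS sub-fits.

    Column j is regressed on all other columns (with intercept);
    tolerance_j = 1 - R^2_j and VIF_j = 1 / tolerance_j, reported as
    ``inf`` when the fit is perfect.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"vif needs more rows than columns for exact OLS "
                         f"sub-fits; got shape ({n}, {p})")
    names = list(column_names) if column_names is not None else [
        f"X{j + 1}" for j in range(p)]
    rows = []
    for j in range(p):
        target = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
        resid = target - A @ coef
        tss = float(np.sum((target - target.mean()) ** 2))
        if tss == 0:
            raise ValueError(f"column {names[j]} is constant")
        r2 = 1.0 - float(resid @ resid) / tss
        tol = max(0.0, 1.0 - r2)
        v = np.inf if tol < 1e-12 else 1.0 / tol
        rows.append({"column": names[j], "tolerance": tol, "vif": v,
                     "flagged": bool(v > VIF_FLAG_THRESHOLD
                                     or tol < TOLERANCE_FLAG_THRESHOLD)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

def enet_objective(beta0: float, beta, D: DesignMatrix,
                   lam: float, alpha: float) -> float:
    """Value of the penalized least-squares objective (1/2N loss scale)."""
    beta = np.asarray(beta, dtype=float)
    r = D.y - beta0 - D.X @ beta
    loss = 0.5 * float(r @ r) / D.n
    penalty = lam * ((1 - alpha) * 0.5 * float(beta @ beta)
                     + alpha * float(np.abs(beta).sum()))
    return loss + penalty


def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@dataclass
class EnetSolution:
    beta: np.ndarray
    intercept: float
    n_iter: int
    converged: bool
    objective_history: np.ndarray | None = None  # per-sweep, when recorded


def fit_enet(
    D: DesignMatrix,
    lam: float,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    warm_start: np.ndarray | None = None,
    record_objective: bool = False,
) -> EnetSolution:
    """Cyclic coordinate descent for the elastic net.

    Each coordinate update is the soft-threshold step
    ``b_j <- S(rho_j, lam*alpha) / (v_j + lam*(1-alpha))`` where
    ``rho_j = (1/N) x_j' r^((-j))`` and ``v_j = (1/N) ||x_j||^2`` (exactly 1
    on standardized columns). Converges when the largest coefficient change
    in a sweep falls below ``tol``; otherwise a ConvergenceWarning is
    issued and the result flagged.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    n, p = D.n, D.p
    # absorb the intercept by centering; a no-op on globally centered data
    # but required for CV sub-fits whose rows are a non-centered subset
    xm = D.X.mean(axis=0)
    ym = float(D.y.mean())
    X = D.X - xm
    y = D.y - ym
    v = np.einsum("ij,ij->j", X, X) / n
    beta = (np.zeros(p) if warm_start is None
            else np.asarray(warm_start, dtype=float).copy())
    r = y - X @ beta
    thresh = lam * alpha
    denom = v + lam * (1 - alpha)
    converged = False
    it = 0
    history: list[float] = []

    def _objective() -> float:
        rr = y - X @ beta
        return (0.5 * float(rr @ rr) / n
                + lam * ((1 - alpha) * 0.5 * float(beta @ beta)
                         + alpha * float(np.abs(beta).sum())))

    if record_objective:
        history.append(_objective())
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            if denom[j] == 0.0:  # constant column in this subset, no penalty
                continue
            bj = beta[j]
            rho = (X[:, j] @ r) / n + v[j] * bj
            new = _soft_threshold(rho, thresh) / denom[j]
            if new != bj:
                r += X[:, j] * (bj - new)
                beta[j] = new
                max_delta = max(max_delta, abs(new - bj))
        if record_objective:
            history.append(_objective())
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"coordinate descent did not converge in {max_iter} sweeps",
                      ConvergenceWarning)
    intercept = ym - float(xm @ beta)
    return EnetSolution(beta=beta, intercept=intercept, n_iter=it, converged=converged,
                        objective_history=np.array(history) if record_objective else None)


def kkt_residual(D: DesignMatrix, beta, lam: float, alpha: float) -> float:
    """Max-norm of the subgradient residual of the objective at ``beta``.

    Zero (to tolerance) certifies optimality: for active coordinates the
    smooth gradient must cancel the penalty subgradient exactly; for zero
    coordinates it must lie within the soft-threshold band lam*alpha.
    """
    beta = np.asarray(beta, dtype=float)
    g = -(D.X.T @ (D.y - D.X @ beta)) / D.n + lam * (1 - alpha) * beta
    res = np.where(
        beta != 0,
        np.abs(g + lam * alpha * np.sign(beta)),
        np.maximum(0.0, np.abs(g) - lam * alpha),
    )
    return float(res.max()) if res.size else 0.0


def lambda_path(D: DesignMatrix, alpha: float, n_lambda: int = 100,
                ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced decreasing penalty grid.

    lambda_max = max_j |x_j' y| / (N * alpha) is the smallest penalty that
    zeroes every coefficient; for alpha = 0 (no sparsity at any finite
    lambda) the grid top uses the small-alpha surrogate.
    """
    if np.allclose(D.y.var(), 0):
        raise ValueError("y has zero variance")
    a = max(alpha, RIDGE_LAMBDA_MAX_SURROGATE)
    lam_max = float(np.max(np.abs(D.X.T @ D.y)) / (D.n * a))
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


@dataclass
class RegularizedFit:
    """Elastic-net path with cross-validation curve and selected model."""

    alpha: float
    lambda_path: np.ndarray
    coef_path: np.ndarray            # p x n_lambda, standardized scale
    intercept_path: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray
    lambda_min: float
    coefficients: np.ndarray         # standardized scale, refit at lambda_min
    intercept: float
    lambda_1se: float                # largest lambda within 1 SE of the minimum
    column_names: list[str]
    k: int
    fold_seed: int
    y_mean: float
    x_mean: np.ndarray
    x_sd: np.ndarray

    @property
    def selected_support(self) -> list[str]:
        return [nm for nm, b in zip(self.column_names, self.coefficients) if b != 0]

    @property
    def support_1se(self) -> list[str]:
        """Support under the one-standard-error rule (sparser; the common
        remedy for the over-selection of the CV-MSE minimizer)."""
        li = int(np.argmin(np.abs(self.lambda_path - self.lambda_1se)))
        return [nm for nm, b in zip(self.column_names, self.coef_path[:, li])
                if b != 0]

    def coefficients_original_scale(self) -> tuple[np.ndarray, float]:
        """(coefficients, intercept) mapped back to the raw predictor scale."""
        b = self.coefficients / self.x_sd
        b0 = self.y_mean + self.intercept - float(b @ self.x_mean)
        return b, b0

    def summary(self) -> dict:
        b_orig, b0_orig = self.coefficients_original_scale()
        return {
            "alpha": self.alpha,
            "lambda_min": self.lambda_min,
            "lambda_1se": self.lambda_1se,
            "k": self.k,
            "fold_seed": self.fold_seed,
            "selected_support": self.selected_support,
            "support_1se": self.support_1se,
            "coefficients_standardized": dict(zip(self.column_names,
                                                  self.coefficients.tolist())),
            "coefficients_original": dict(zip(self.column_names, b_orig.tolist())),
            "intercept_original": b0_orig,
        }


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [fold for fold in np.array_split(order, k)]


def cross_validate(
    D: DesignMatrix,
    alpha: float = 0.5,
    k: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    ratio: float = 1e-4,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> RegularizedFit:
    """k-fold CV over the lambda path; refit on all data at the minimizer.

    Folds come from a seeded random partition. For each lambda the held-out
    MSE mean and standard error across folds are recorded; lambda_min is
    the grid value minimizing the mean, with ties broken toward the larger
    (sparser) lambda. Warm starts propagate along the path.
    """
    if not (2 <= k <= D.n):
        raise ValueError(f"k must be in [2, n={D.n}], got {k}")
    lams = lambda_path(D, alpha, n_lambda=n_lambda, ratio=ratio)
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(D.n, k, rng)
    fold_mse = np.empty((k, lams.size))
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(D.n, dtype=bool)
        train_mask[test_idx] = False
        Dt = DesignMatrix(X=D.X[train_mask], y=D.y[train_mask],
                          column_names=D.column_names, x_mean=D.x_mean,
                          x_sd=D.x_sd, y_mean=D.y_mean)
        Xte, yte = D.X[test_idx], D.y[test_idx]
        beta = np.zeros(D.p)
        for li, lam in enumerate(lams):
            sol = fit_enet(Dt, lam, alpha, tol=tol, max_iter=max_iter,
                           warm_start=beta)
            beta = sol.beta
            pred = sol.intercept + Xte @ beta
            fold_mse[f, li] = float(np.mean((yte - pred) ** 2))
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    # grid is decreasing, so the first argmin is the largest (sparsest) tie
    best = int(np.argmin(cv_mean))
    lam_min = float(lams[best])
    within = np.flatnonzero(cv_mean <= cv_mean[best] + cv_se[best])
    lam_1se = float(lams[within.min()])  # largest lambda inside one SE

    coef_path = np.empty((D.p, lams.size))
    intercept_path = np.empty(lams.size)
    beta = np.zeros(D.p)
    for li, lam in enumerate(lams):
        sol = fit_enet(D, lam, alpha, tol=tol, max_iter=max_iter, warm_start=beta)
        beta = sol.beta
        coef_path[:, li] = beta
        intercept_path[li] = sol.intercept
    final = fit_enet(D, lam_min, alpha, tol=tol, max_iter=max_iter,
                     warm_start=coef_path[:, best])
    return RegularizedFit(
        alpha=alpha, lambda_path=lams, coef_path=coef_path,
        intercept_path=intercept_path, cv_mse_mean=cv_mean, cv_mse_se=cv_se,
        lambda_min=lam_min, coefficients=final.beta, intercept=final.intercept,
        lambda_1se=lam_1se,
        column_names=list(D.column_names), k=k, fold_seed=seed,
        y_mean=D.y_mean, x_mean=D.x_mean, x_sd=D.x_sd,
    )


@dataclass
class SupportOverlap:
    """Agreement between the selected supports of two fits."""

    intersection: list[str]
    symmetric_difference: list[str]
    jaccard: float
    coefficient_deltas: dict

    @classmethod
    def empty_agreement(cls) -> "SupportOverlap":
        return cls([], [], 1.0, {})


def compare_supports(fit_a: RegularizedFit, fit_b: RegularizedFit) -> SupportOverlap:
    """Intersection, symmetric difference, Jaccard overlap, and per-column
    coefficient deltas (standardized scale) of two selected supports."""
    sa, sb = set(fit_a.selected_support), set(fit_b.selected_support)
    union = sa | sb
    inter = sa & sb
    jac = 1.0 if not union else len(inter) / len(union)
    ca = dict(zip(fit_a.column_names, fit_a.coefficients))
    cb = dict(zip(fit_b.column_names, fit_b.coefficients))
    deltas = {nm: float(cb.get(nm, 0.0) - ca.get(nm, 0.0)) for nm in sorted(union)}
    return SupportOverlap(
        intersection=sorted(inter),
        symmetric_difference=sorted(sa ^ sb),
        jaccard=float(jac),
        coefficient_deltas=deltas,
    )
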