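"""LASSO prediction of the speed of forgetting from connectivity features.

The 45 DMN-anchored partial-correlation edges are regressed on participant
SoF with an L1-penalized linear model,

    β̂ = argmin_β  (1/2n)‖y − β₀ − Xβ‖₂² + λ‖β‖₁,

with λ chosen by leave-one-out cross-validation over a 100-point log grid
from λ_max (the smallest penalty that zeroes every coefficient) down four
decades, ties resolved toward the sparser model.  Features are standardized
to unit variance inside the solver and coefficients reported on the original
scale; the intercept is unpenalized.  The validation battery mirrors the
reference analysis: LOO prediction with the support fixed to the final
model's selected features (weights refit by ordinary least squares on each
training fold), refits after removing selected features, variance inflation
factors, and a permutation null obtained by shuffling the SoF vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

__all__ = [
    "LassoReport",
    "PermutationReport",
    "lambda_max",
    "lasso_path_fit",
    "select_lambda_loo",
    "final_fit_and_report",
    "loo_validate",
    "feature_removal_test",
    "vif",
    "permutation_test",
]

N_GRID = 100
GRID_DECADES = 4.0
SOLVER_TOL = 1e-7  # final fits
CV_TOL = 1e-5  # path solves inside LOO λ selection (curve-insensitive)


@dataclass(frozen=True)
class LassoReport:
    """Fitted model summary: penalty, weights, and in/out-of-sample fit."""

    lambda_selected: float
    beta: pd.Series  # original-scale weights, canonical feature order
    intercept: float
    fitted_r: float
    loo_r: float | None  # None when the selected support is empty
    n_selected: int
    loo_predictions: np.ndarray | None = None
    cv_curve: pd.Series | None = None  # LOO MSE per grid λ

    @property
    def selected(self) -> list[str]:
        return [f for f, b in self.beta.items() if b != 0.0]

    @property
    def is_null(self) -> bool:
        """True when the model reduces to the intercept (no feature selected)."""
        return self.n_selected == 0


@dataclass(frozen=True)
class PermutationReport:
    n_shuffles: int
    frac_null_models: float
    frac_converged: float
    frac_comparable: float
    empirical_p: float
    observed_fitted_r: float


def _validate(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in inputs")
    return X, y


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero:
    max_j |⟨x_j, y − ȳ⟩|/n on standardized features."""
    X, y = _validate(X, y)
    Xs, _, _ = _standardize(X)
    n = len(y)
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)


def lambda_grid(X: np.ndarray, y: np.ndarray, n_grid: int = N_GRID) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax <= 0:
        raise ValueError("degenerate problem: lambda_max is 0")
    return np.logspace(np.log10(lmax), np.log10(lmax) - GRID_DECADES, n_grid)


def lasso_path_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    feature_names: Sequence[str] | None = None,
) -> tuple[pd.Series, float]:
    """Solve the L1-penalized least-squares problem at a single penalty.

    Features are standardized internally; the returned coefficients are on
    the original scale and the intercept is unpenalized.  At λ = 0 the
    solution coincides with ordinary least squares (p < n).
    """
    X, y = _validate(X, y)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(p)
    ]
    Xs, mu, sd = _standardize(X)
    yc = y - y.mean()
    if lam <= 0:
        beta_s, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    else:
        model = Lasso(alpha=lam, fit_intercept=False, tol=SOLVER_TOL,
                      max_iter=100_000)
        model.fit(Xs, yc)
        beta_s = model.coef_
    beta = beta_s / sd
    intercept = float(y.mean() - beta @ mu)
    return pd.Series(beta, index=names), intercept


def select_lambda_loo(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[float, pd.Series]:
    """Choose λ by minimizing leave-one-out prediction MSE over the grid.

    Each training fold is standardized on its own; the per-fold solution path
    is computed by coordinate descent across the whole grid at once.  Ties in
    the CV curve resolve toward the larger λ (sparser model).
    """
    X, y = _validate(X, y)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 observations for LOO selection")
    if y.std() == 0:
        raise ValueError("y has zero variance")
    if grid is None:
        grid = lambda_grid(X, y)
    grid = np.asarray(grid, dtype=float)
    order = np.argsort(grid)[::-1]  # lasso_path wants decreasing alphas
    grid_desc = grid[order]
    sq_err = np.zeros((n, len(grid)))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        Xs, mu, sd = _standardize(Xtr)
        ybar = ytr.mean()
        _, coefs, _ = lasso_path(
            Xs, ytr - ybar, alphas=grid_desc, tol=CV_TOL, max_iter=100_000,
            precompute=True,
        )
        xi = (X[i] - mu) / sd
        preds = ybar + xi @ coefs  # (n_grid,) in descending-λ order
        sq_err[i, order] = (y[i] - preds) ** 2
    cv = sq_err.mean(axis=0)
    best = np.min(cv)
    # ties toward the larger λ
    lam = float(np.max(grid[cv <= best + 1e-15]))
    return lam, pd.Series(cv, index=grid)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def loo_validate(
    X: np.ndarray,
    y: np.ndarray,
    support: Sequence[int],
) -> tuple[np.ndarray, float | None]:
    """Leave-one-out validation with the feature support held fixed.

    For each participant, the weights of the selected features are refit by
    unpenalized least squares on the remaining n−1 and applied to the
    held-out row.  Returns the held-out predictions and their Pearson
    correlation with the observed values (None for an empty support or
    degenerate predictions).
    """
    X, y = _validate(X, y)
    support = list(support)
    if not support:
        return np.full(len(y), np.nan), None
    Xsel = X[:, support]
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        A = np.column_stack([np.ones(n - 1), Xsel[mask]])
        coef, *_ = np.linalg.lstsq(A, y[mask], rcond=None)
        preds[i] = coef[0] + Xsel[i] @ coef[1:]
    r = _pearson(preds, y)
    return preds, (None if np.isnan(r) else r)


def final_fit_and_report(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    grid: np.ndarray | None = None,
) -> LassoReport:
    """CV-select λ, refit on the full sample, and run LOO validation."""
    X, y = _validate(X, y)
    lam, cv = select_lambda_loo(X, y, grid)
    beta, intercept = lasso_path_fit(X, y, lam, feature_names)
    fitted = intercept + X @ beta.to_numpy()
    fitted_r = _pearson(fitted, y)
    support = [j for j, b in enumerate(beta.to_numpy()) if b != 0.0]
    loo_preds, loo_r = loo_validate(X, y, support)
    return LassoReport(
        lambda_selected=lam,
        beta=beta,
        intercept=intercept,
        fitted_r=fitted_r,
        loo_r=loo_r,
        n_selected=len(support),
        loo_predictions=loo_preds,
        cv_curve=cv,
    )


def feature_removal_test(
    X: np.ndarray,
    y: np.ndarray,
    removed: Sequence[str],
    feature_names: Sequence[str],
) -> LassoReport:
    """Re-run λ selection and the final fit with some features removed.

    Used both for the remove-all-selected check (does any other feature set
    carry the signal?) and the remove-one-at-a-time stability checks.  The
    returned report's ``is_null`` flags an intercept-only (non-converged)
    outcome.
    """
    X, y = _validate(X, y)
    names = list(feature_names)
    unknown = set(removed) - set(names)
    if unknown:
        raise KeyError(f"unknown features: {sorted(unknown)}")
    keep = [j for j, f in enumerate(names) if f not in set(removed)]
    if not keep:
        raise ValueError("cannot remove every feature")
    return final_fit_and_report(X[:, keep], y, [names[j] for j in keep])


def vif(
    X_selected: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> dict[str, float]:
    """Variance inflation factor 1/(1−R²_j) per selected feature.

    R²_j comes from regressing feature j (with intercept) on the other
    selected features.  Perfect collinearity yields inf, not an exception.
    """
    X = np.asarray(X_selected, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 features")
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p={p})")
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(p)
    ]
    out: dict[str, float] = {}
    for j in range(p):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ coef
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        if tss == 0:
            out[names[j]] = float("inf")
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        out[names[j]] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
    observed_fitted_r: float | None = None,
) -> PermutationReport:
    """Permutation null for the whole selection-plus-fit procedure.

    The SoF vector is shuffled ``n_shuffles`` times and the full LOO λ
    selection and refit repeated on each shuffle.  A shuffle yielding an
    intercept-only model counts as "failed to converge"; among converged
    shuffles, those with fitted correlation at least the observed one count
    as comparable.  The empirical p uses the add-one correction
    (1 + #comparable)/(1 + n_shuffles).
    """
    X, y = _validate(X, y)
    rng = np.random.default_rng(seed)
    if observed_fitted_r is None:
        observed_fitted_r = final_fit_and_report(X, y).fitted_r
    n_null = 0
    n_comparable = 0
    for _ in range(n_shuffles):
        y_perm = rng.permutation(y)
        try:
            rep = final_fit_and_report(X, y_perm)
        except ValueError:
            n_null += 1
            continue
        if rep.is_null:
            n_null += 1
        elif rep.fitted_r >= observed_fitted_r:
            n_comparable += 1
    frac_null = n_null / n_shuffles if n_shuffles else 0.0
    return PermutationReport(
        n_shuffles=n_shuffles,
        frac_null_models=frac_null,
        frac_converged=1.0 - frac_null,
        frac_comparable=n_comparable / n_shuffles if n_shuffles else 0.0,
        empirical_p=(1 + n_comparable) / (1 + n_shuffles),
        observed_fitted_r=observed_fitted_r,
    )
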