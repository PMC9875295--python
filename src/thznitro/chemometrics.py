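"""PLS regression engine, cross-validation, and evaluation metrics.

Partial least-squares is the workhorse behind all three band selectors
and the split comparison. The engine is a compact single-response NIPALS
(column centering, no scaling): per component the X-weight is the
normalized covariance direction X'y, scores/loadings follow, and X and y
are deflated; the regression vector is b = W (P'W)^{-1} q. The selector
loops refit PLS thousands of times on small matrices, so the engine is
plain vectorized numpy; its coefficients agree with scikit-learn's
``PLSRegression(scale=False)`` to machine precision (asserted in the
test suite) and with OLS when the component count reaches the rank of X.

The evaluation metrics follow the conventions of the THz nitrogen
workflow: RMSE uses an (n-1) denominator,

    RMSE = sqrt( sum (y - yhat)^2 / (n - 1) ),

which is unconventional but is the form this workflow reports; a
``denominator="n"`` switch restores comparability with other software.
R^2 is the usual 1 - SSE/SST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls",
    "feasible_components",
    "rmse",
    "r_squared",
    "cross_validate",
    "loo_coefficient_matrix",
]

_TOL = 1e-14  # residual-exhaustion cutoff inside NIPALS


@dataclass
class PLSModel:
    """Fitted PLS state: centering vectors, latent directions, coefficients."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (p, A) X-weights, unit norm per component
    x_loadings: np.ndarray    # (p, A)
    y_loadings: np.ndarray    # (A,)
    coefficients: np.ndarray  # (p,) regression vector b

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coefficients + self.y_mean


@dataclass
class CVResult:
    """Cross-validation outcome: held-out predictions (in sample order) and RMSECV."""

    rmsecv: float
    per_fold_predictions: np.ndarray
    scheme: str


def feasible_components(X: np.ndarray, n_components: int) -> int:
    """Clip a requested component count to what the data can support."""
    n, p = np.atleast_2d(X).shape
    return max(1, min(n_components, n - 1, p))


def _nipals_coef(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Regression vector only — fast path for the selector loops.

    Same algorithm as :func:`fit_pls` without building the model object.
    X and y must already be float arrays; they are not modified.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    p = Xc.shape[1]
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    Q = np.empty(n_components)
    a = 0
    for _ in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < _TOL:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt < _TOL:
            break
        pa = (Xc.T @ t) / tt
        qa = (yc @ t) / tt
        W[:, a], P[:, a], Q[a] = w, pa, qa
        Xc -= np.outer(t, pa)
        yc = yc - qa * t
        a += 1
    if a == 0:
        return np.zeros(p)
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa)


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a single-response PLS regression with ``n_components`` latent variables.

    Deterministic; successive score vectors are mutually orthogonal, and
    with as many components as the rank of centered X the predictions
    coincide with ordinary least squares. If the residual is exhausted
    before the requested count (rank-deficient X or constant y), the
    remaining components are zero.

    Raises
    ------
    ValueError
        If ``n_components`` exceeds the feasible bound min(n-1, p).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError(f"X has {n} rows but y has {y.size} entries")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds feasible rank min(n-1, p)="
            f"{min(n - 1, p)}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    weights = np.zeros((p, n_components))
    x_loadings = np.zeros((p, n_components))
    y_loadings = np.zeros(n_components)
    a = 0
    for _ in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < _TOL:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt < _TOL:
            break
        pa = (Xc.T @ t) / tt
        qa = (yc @ t) / tt
        weights[:, a], x_loadings[:, a], y_loadings[a] = w, pa, qa
        Xc -= np.outer(t, pa)
        yc = yc - qa * t
        a += 1
    if a == 0:
        coef = np.zeros(p)
    else:
        Wa, Pa, Qa = weights[:, :a], x_loadings[:, :a], y_loadings[:a]
        coef = Wa @ np.linalg.solve(Pa.T @ Wa, Qa)
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=weights,
        x_loadings=x_loadings,
        y_loadings=y_loadings,
        coefficients=coef,
    )


def rmse(y: np.ndarray, yhat: np.ndarray, denominator: str = "n-1") -> float:
    """Root-mean-square error with an (n-1) denominator by default.

    ``denominator="n"`` gives the conventional mean-square form.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("y and yhat must have equal length")
    if denominator not in ("n-1", "n"):
        raise ValueError("denominator must be 'n-1' or 'n'")
    n = y.size
    if denominator == "n-1" and n < 2:
        raise ValueError("RMSE with an (n-1) denominator needs n >= 2")
    if n < 1:
        raise ValueError("need at least one observation")
    div = n - 1 if denominator == "n-1" else n
    return float(np.sqrt(np.sum((y - yhat) ** 2) / div))


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE/SST. Errors on constant y."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("y and yhat must have equal length")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for a constant reference vector")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scheme: str = "loo",
    n_folds: int = 10,
    seed: int = 0,
    clip_components: bool = True,
) -> CVResult:
    """Held-out prediction of every sample by LOO or seeded k-fold CV.

    ``scheme="loo"`` refits without each sample in turn; ``scheme="kfold"``
    shuffles sample order with ``seed`` and cuts contiguous folds
    (``n_folds=n`` reduces exactly to LOO). Each held-out sample is
    predicted by a model that never saw it; RMSECV uses the package RMSE
    (n-1 denominator) over the assembled held-out predictions.

    ``clip_components`` silently lowers the component count when a
    training fold is too small to support it (needed deep inside the
    selector loops); with ``clip_components=False`` an infeasible count
    raises instead.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
        scheme_name = "LOO"
    elif scheme == "kfold":
        if n_folds > n:
            raise ValueError(f"n_folds={n_folds} exceeds sample count {n}")
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [test for _, test in kf.split(X)]
        scheme_name = f"KFOLD({n_folds})"
    else:
        raise ValueError("scheme must be 'loo' or 'kfold'")

    yhat = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for test in folds:
        mask[:] = True
        mask[test] = False
        Xtr, ytr = X[mask], y[mask]
        a = feasible_components(Xtr, n_components)
        if not clip_components and a != n_components:
            raise ValueError("n_components infeasible for a training fold")
        coef = _nipals_coef(Xtr, ytr, a)
        yhat[test] = (X[test] - Xtr.mean(axis=0)) @ coef + ytr.mean()
    return CVResult(rmsecv=rmse(y, yhat), per_fold_predictions=yhat, scheme=scheme_name)


def loo_coefficient_matrix(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Leave-one-out PLS coefficient matrix: row i is b from the fit excluding sample i."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    L = np.empty((n, p))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[:] = True
        mask[i] = False
        a = feasible_components(X[mask], n_components)
        L[i] = _nipals_coef(X[mask], y[mask], a)
    return L
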