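"""Calibration models: exact-design RBF network and a small backpropagation network.

The RBF network follows the exact-design construction (MATLAB's
``newrbe`` convention): one Gaussian unit per calibration sample,

    a_i(x) = exp( -(0.8326 * ||x - c_i|| / spread)^2 ),

so a unit's activation falls to 0.5 at distance ``spread`` from its
center ("expansion speed"). The output layer [W; b2] is obtained by
solving the linear system A_aug w = y in the least-squares sense, where
A_aug is the Q x (Q+1) activation matrix with a bias column — an
underdetermined system, hence (numerically) exact interpolation of the
calibration responses at every spread.

The BPNN is a single-hidden-layer perceptron (tanh hidden units, linear
output) trained by full-batch gradient descent on mean squared error,
with min-max normalization of inputs and output to [-1, 1] computed on
calibration statistics only. Weight initialization is seeded, making
training deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .chemometrics import r_squared, rmse
from .io_formats import FitReport, SpectraSet
from .partitioning import SplitResult

__all__ = [
    "RBFModel",
    "BPNNModel",
    "rbf_train",
    "rbf_predict",
    "rbf_spread_sweep",
    "bpnn_train",
    "bpnn_predict",
    "evaluate_model",
]

#: exp(-(0.8326)^2) = 0.5 — makes `spread` the half-activation radius.
_RBF_BETA = 0.8326


# ---------------------------------------------------------------------------
# RBF network


@dataclass
class RBFModel:
    """Exact-design RBF state: all calibration samples as centers, linear output."""

    centers: np.ndarray  # (Q, p)
    spread: float
    weights: np.ndarray  # (Q,)
    bias: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return rbf_predict(self, X)


def _activations(centers: np.ndarray, X: np.ndarray, spread: float) -> np.ndarray:
    d = cdist(np.atleast_2d(X), centers)
    return np.exp(-((_RBF_BETA * d / spread) ** 2))


def rbf_train(X_cal: np.ndarray, y_cal: np.ndarray, spread: float = 0.5) -> RBFModel:
    """Fit the exact-design RBF network at a given spread.

    Every calibration sample becomes a center; output weights and bias
    solve the activation system by (min-norm) least squares. An
    ill-conditioned activation matrix is tolerated — the SVD-based solve
    still minimizes the residual — with a warning.
    """
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    if spread <= 0:
        raise ValueError("spread must be > 0")
    q = X_cal.shape[0]
    if q != y_cal.size:
        raise ValueError("X_cal and y_cal disagree on the number of samples")
    A = _activations(X_cal, X_cal, spread)  # (Q, Q)
    A_aug = np.hstack([A, np.ones((q, 1))])
    sol, residual, rank, _ = np.linalg.lstsq(A_aug, y_cal, rcond=None)
    if rank < q:
        warnings.warn(
            f"RBF activation matrix numerically rank-deficient ({rank}/{q}) at "
            f"spread={spread:g}",
            stacklevel=2,
        )
    return RBFModel(centers=X_cal.copy(), spread=float(spread), weights=sol[:q], bias=float(sol[q]))


def rbf_predict(model: RBFModel, X: np.ndarray) -> np.ndarray:
    """Forward pass: Gaussian activations against the stored centers, linear output."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match centers ({model.centers.shape[1]})"
        )
    return _activations(model.centers, X, model.spread) @ model.weights + model.bias


def rbf_spread_sweep(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    spreads: np.ndarray | None = None,
    cv_indices: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Scan candidate spreads; report calibration RMSE (RMSEC) per spread.

    By default scans 0.1 to 1.0 in steps of 0.1. Because the exact design
    interpolates the calibration set, RMSEC is near zero for every spread
    and cannot discriminate; passing ``cv_indices=(train, val)`` adds a
    held-out RMSE column (``rmse_val``) on which the returned
    ``best_spread`` is then based.

    Returns a dict with ``spreads``, ``rmsec`` (and ``rmse_val`` when
    validated), and ``best_spread``.
    """
    if spreads is None:
        spreads = np.round(np.arange(0.1, 1.01, 0.1), 10)
    spreads = np.asarray(spreads, dtype=float)
    if spreads.size == 0:
        raise ValueError("spread list must be non-empty")
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y_cal = np.asarray(y_cal, dtype=float).ravel()

    rmsec = np.empty(spreads.size)
    rmse_val = np.empty(spreads.size) if cv_indices is not None else None
    for k, s in enumerate(spreads):
        if cv_indices is None:
            model = rbf_train(X_cal, y_cal, s)
            rmsec[k] = rmse(y_cal, rbf_predict(model, X_cal))
        else:
            tr, va = cv_indices
            model = rbf_train(X_cal[tr], y_cal[tr], s)
            rmsec[k] = rmse(y_cal[tr], rbf_predict(model, X_cal[tr]))
            rmse_val[k] = rmse(y_cal[va], rbf_predict(model, X_cal[va]))
    crit = rmse_val if rmse_val is not None else rmsec
    best = int(np.argmin(crit))
    out = {"spreads": spreads, "rmsec": rmsec, "best_spread": float(spreads[best])}
    if rmse_val is not None:
        out["rmse_val"] = rmse_val
    return out


# ---------------------------------------------------------------------------
# BPNN


@dataclass
class BPNNModel:
    """Single-hidden-layer perceptron with min-max [-1, 1] scaling.

    Defaults mirror the THz nitrogen calibration setup: 6 hidden
    neurons, learning rate 0.01; ``max_epochs`` is a budget, with early
    stopping on a loss plateau.
    """

    hidden_size: int = 6
    learning_rate: float = 0.01
    max_epochs: int = 22
    plateau_tol: float = 1e-8
    # fitted state
    w1: np.ndarray | None = None
    b1: np.ndarray | None = None
    w2: np.ndarray | None = None
    b2: float = 0.0
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None
    y_min: float = 0.0
    y_max: float = 1.0
    loss_curve: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return bpnn_predict(self, X)


def _minmax_scale(v: np.ndarray, lo: np.ndarray | float, hi: np.ndarray | float) -> np.ndarray:
    span = np.where(np.asarray(hi) - np.asarray(lo) > 0, np.asarray(hi) - np.asarray(lo), 1.0)
    return 2.0 * (v - lo) / span - 1.0


def _minmax_unscale(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo if hi > lo else 1.0
    return (v + 1.0) / 2.0 * span + lo


def bpnn_train(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    params: BPNNModel | None = None,
    seed: int = 0,
) -> BPNNModel:
    """Train the BPNN by seeded full-batch backpropagation.

    Inputs and output are min-max scaled to [-1, 1] on calibration
    statistics; hidden layer is tanh, output linear. Training stops at
    ``max_epochs`` or when the relative loss improvement falls below
    ``plateau_tol``. Identical seeds give identical weights.
    """
    base = params if params is not None else BPNNModel()
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    if not (np.all(np.isfinite(X_cal)) and np.all(np.isfinite(y_cal))):
        raise ValueError("training data must be finite")
    if np.ptp(y_cal) == 0:
        raise ValueError("constant response: nothing to learn")

    model = BPNNModel(
        hidden_size=base.hidden_size,
        learning_rate=base.learning_rate,
        max_epochs=base.max_epochs,
        plateau_tol=base.plateau_tol,
    )
    model.x_min, model.x_max = X_cal.min(axis=0), X_cal.max(axis=0)
    model.y_min, model.y_max = float(y_cal.min()), float(y_cal.max())
    Xs = _minmax_scale(X_cal, model.x_min, model.x_max)
    ys = _minmax_scale(y_cal, model.y_min, model.y_max)

    n, p = Xs.shape
    h = model.hidden_size
    rng = np.random.default_rng(seed)
    # Nguyen-Widrow-flavored small init keeps tanh units in their linear range
    w1 = rng.uniform(-0.5, 0.5, size=(p, h)) / max(1.0, np.sqrt(p))
    b1 = rng.uniform(-0.5, 0.5, size=h)
    w2 = rng.uniform(-0.5, 0.5, size=h) / np.sqrt(h)
    b2 = 0.0

    losses = []
    prev = np.inf
    for _ in range(model.max_epochs):
        hidden = np.tanh(Xs @ w1 + b1)           # (n, h)
        yhat = hidden @ w2 + b2
        err = yhat - ys
        loss = float(np.mean(err**2))
        losses.append(loss)

        # backprop of mean squared error
        g_out = 2.0 * err / n                     # (n,)
        gw2 = hidden.T @ g_out
        gb2 = g_out.sum()
        g_hidden = np.outer(g_out, w2) * (1.0 - hidden**2)
        gw1 = Xs.T @ g_hidden
        gb1 = g_hidden.sum(axis=0)

        lr = model.learning_rate
        w1 -= lr * gw1
        b1 -= lr * gb1
        w2 -= lr * gw2
        b2 -= lr * gb2

        if np.isfinite(prev) and 0 <= prev - loss <= model.plateau_tol * max(prev, 1e-300):
            break
        prev = loss

    model.w1, model.b1, model.w2, model.b2 = w1, b1, w2, float(b2)
    model.loss_curve = np.asarray(losses)
    return model


def bpnn_predict(model: BPNNModel, X: np.ndarray) -> np.ndarray:
    """Forward pass: scale, tanh hidden layer, linear output, unscale."""
    if model.w1 is None:
        raise ValueError("model is not trained")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.w1.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match the trained network "
            f"({model.w1.shape[0]})"
        )
    Xs = _minmax_scale(X, model.x_min, model.x_max)
    ys = np.tanh(Xs @ model.w1 + model.b1) @ model.w2 + model.b2
    return _minmax_unscale(ys, model.y_min, model.y_max)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_model(
    model: RBFModel | BPNNModel,
    data: SpectraSet,
    split: SplitResult,
    selection: np.ndarray | None,
    model_name: str | None = None,
    selection_name: str = "none",
) -> FitReport:
    """Score a trained model on a split: RMSEC/Rc2 on calibration, RMSEP/Rp2 on prediction.

    ``selection`` restricts the spectra to the chosen variable indices
    (None means the full spectrum). The model must have been trained on
    the same selection and calibration samples.
    """
    if len(split.pred_indices) == 0:
        raise ValueError("empty prediction set")
    cols = np.asarray(selection, dtype=int) if selection is not None else slice(None)
    cal, pred = split.cal_indices, split.pred_indices
    X_cal = data.power[cal][:, cols]
    X_pred = data.power[pred][:, cols]
    y_cal = data.nitrogen_pct[cal]
    y_pred = data.nitrogen_pct[pred]

    yhat_cal = model.predict(X_cal)
    yhat_pred = model.predict(X_pred)
    return FitReport(
        rmsec_pct=rmse(y_cal, yhat_cal),
        rmsep_pct=rmse(y_pred, yhat_pred),
        r2_cal=r_squared(y_cal, yhat_cal),
        r2_pred=r_squared(y_pred, yhat_pred),
        model_name=model_name or type(model).__name__,
        selection_name=selection_name,
        n_cal=len(cal),
        n_pred=len(pred),
    )
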