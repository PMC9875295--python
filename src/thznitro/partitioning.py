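"""Calibration/prediction set partitioning: Kennard-Stone and random sampling.

Kennard-Stone (KS) is the deterministic maximin procedure: seed the
calibration set with the two most distant spectra (Euclidean distance in
spectral space), then repeatedly admit the candidate whose distance to
its nearest already-selected sample is largest, so the calibration set
spans the spectral space evenly. Random sampling (RS) draws the
calibration set uniformly without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemometrics import cross_validate, feasible_components, r_squared
from .io_formats import SpectraSet

__all__ = ["SplitResult", "euclidean_distance", "ks_split", "rs_split", "compare_splits"]


@dataclass
class SplitResult:
    """Calibration/prediction index partition and the method that produced it.

    ``cal_indices`` preserves KS selection order; the two index sets are
    disjoint and jointly cover all samples.
    """

    cal_indices: list[int]
    pred_indices: list[int]
    method: str  # "KS" or "RS"
    seed: int | None = None

    def __post_init__(self) -> None:
        cal, pred = set(self.cal_indices), set(self.pred_indices)
        if len(cal) != len(self.cal_indices) or len(pred) != len(self.pred_indices):
            raise ValueError("duplicate indices within a partition")
        if cal & pred:
            raise ValueError("calibration and prediction sets must be disjoint")
        n = len(cal) + len(pred)
        if cal | pred != set(range(n)):
            raise ValueError("partition must cover indices 0..N-1 exactly")
        if self.method not in ("KS", "RS"):
            raise ValueError("method must be 'KS' or 'RS'")

    @property
    def n_total(self) -> int:
        return len(self.cal_indices) + len(self.pred_indices)

    def to_dict(self) -> dict:
        return {
            "cal_indices": [int(i) for i in self.cal_indices],
            "pred_indices": [int(i) for i in self.pred_indices],
            "method": self.method,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitResult":
        return cls(**d)


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two spectra, sqrt(sum_j (a_j - b_j)^2)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return float(np.linalg.norm(a - b))


def ks_split(data: SpectraSet, n_cal: int) -> SplitResult:
    """Kennard-Stone maximin partition into ``n_cal`` calibration samples.

    Fully deterministic: the first two picks are the global max-distance
    pair; every later pick maximizes the minimum distance to the current
    calibration set. Ties break toward the lowest sample index, which is
    also the order numpy's argmax reports.
    """
    n = data.n_samples
    # n_cal == n is permitted (every sample calibrates; empty prediction set)
    if not 2 <= n_cal <= n:
        raise ValueError(f"n_cal must satisfy 2 <= n_cal <= {n}, got {n_cal}")
    X = data.power
    # pairwise squared distances; monotone in true distance so argmax agrees
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)

    first = int(np.argmax(d2))
    i, j = divmod(first, n)
    if i > j:  # argmax of the symmetric matrix: keep the (low, high) orientation
        i, j = j, i
    selected = [i, j]
    min_d2 = np.minimum(d2[i], d2[j])
    min_d2[selected] = -1.0
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_d2))
        selected.append(nxt)
        min_d2 = np.minimum(min_d2, d2[nxt])
        min_d2[nxt] = -1.0
    pred = sorted(set(range(n)) - set(selected))
    return SplitResult(cal_indices=selected, pred_indices=pred, method="KS")


def rs_split(data: SpectraSet, n_cal: int, seed: int = 0) -> SplitResult:
    """Uniform random partition without replacement; deterministic given seed."""
    n = data.n_samples
    if not 1 <= n_cal < n:
        raise ValueError(f"n_cal must satisfy 1 <= n_cal < {n}, got {n_cal}")
    rng = np.random.default_rng(seed)
    cal = rng.choice(n, size=n_cal, replace=False)
    pred = sorted(set(range(n)) - set(cal.tolist()))
    return SplitResult(
        cal_indices=[int(i) for i in cal], pred_indices=pred, method="RS", seed=seed
    )


def compare_splits(
    data: SpectraSet, split: SplitResult, n_components: int = 5
) -> tuple[float, float]:
    """Leave-one-out PLS quality of a calibration set: (R^2, RMSECV).

    Fits the shared PLS engine on the calibration samples with
    leave-one-out cross-validation and scores the held-out predictions,
    enabling the KS-vs-RS representativeness comparison.
    """
    cal = data.subset(split.cal_indices)
    y = cal.nitrogen_pct
    if np.allclose(y, y.mean()):
        raise ValueError("degenerate calibration set: constant nitrogen reference")
    a = feasible_components(cal.power, n_components)
    cv = cross_validate(cal.power, y, a, scheme="loo")
    return r_squared(y, cv.per_fold_predictions), cv.rmsecv
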