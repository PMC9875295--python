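"""Characteristic-frequency-band selection: UVE, SCARS, and iPLS.

All three selectors rank or partition the frequency grid using PLS
regression of nitrogen content on the (smoothed) power spectra of the
calibration set, and return index subsets plus per-algorithm diagnostics.

* **UVE** (uninformative variable elimination) appends an artificial
  noise block of the same width as the spectrum, computes the
  leave-one-out PLS coefficient matrix on the augmented data, and keeps
  the real variables whose coefficient stability ``S_i = mean(b_i)/std(b_i)``
  exceeds the largest stability seen anywhere in the noise block.
* **SCARS** (stability competitive adaptive reweighted sampling)
  iteratively shrinks the variable set: per run, Monte-Carlo resampling
  of the calibration samples yields a per-variable stability
  ``c_j = |mean(b_j)| / sd(b_j)`` over the resampled fits; an exponential
  decay function fixes the fraction of variables force-retained, adaptive
  reweighted sampling (probability proportional to ``c_j``) trims the
  remainder, and the run's subset is scored by k-fold RMSECV. The subset
  with the smallest RMSECV wins.
* **iPLS** (interval PLS) tiles the grid into equidistant contiguous
  intervals, cross-validates a local PLS model per interval, and keeps
  the interval with the lowest RMSECV; a wrapper searches over the
  interval count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chemometrics import (
    _nipals_coef,
    cross_validate,
    feasible_components,
    loo_coefficient_matrix,
)

__all__ = [
    "UVEResult",
    "SCARSResult",
    "IPLSResult",
    "uve_select",
    "scars_select",
    "ipls_select",
    "ipls_interval_search",
    "edf_schedule",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class UVEResult:
    """UVE diagnostics: stabilities of real and noise variables, threshold, picks."""

    stability: np.ndarray        # (p,) real-variable stabilities
    noise_stability: np.ndarray  # (p,) artificial-variable stabilities
    threshold: float
    selected: np.ndarray         # sorted indices into the real variables


@dataclass
class SCARSResult:
    """SCARS trace: per-run subsets and RMSECVs, plus the winning subset."""

    runs: int
    per_run_subsets: list[np.ndarray]
    per_run_rmsecv: np.ndarray
    best_run: int
    selected: np.ndarray


@dataclass
class IPLSResult:
    """iPLS table: interval bounds, per-interval RMSECV, winning interval/indices."""

    n_intervals: int
    interval_bounds_thz: list[tuple[float, float]]
    interval_indices: list[np.ndarray]
    per_interval_rmsecv: np.ndarray
    best_interval: int
    selected: np.ndarray


# ---------------------------------------------------------------------------
# UVE


def uve_select(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    noise_scale: float = 1e-10,
    threshold_factor: float = 1.0,
    seed: int = 0,
) -> UVEResult:
    """Uninformative variable elimination with an artificial-noise reference.

    A uniform(0, ``noise_scale``) noise matrix of the same shape as X is
    appended column-wise (the tiny scale leaves the PLS fit untouched;
    stability is scale-free per column). The leave-one-out coefficient
    matrix of the augmented data gives per-column stabilities
    ``S = mean(b)/std(b)``; the screening threshold is
    ``threshold_factor`` times the largest absolute stability inside the
    noise block, and real variables with ``|S| > threshold`` are kept.

    ``n_components`` defaults to a deliberately small latent rank: with
    heavily collinear spectra, higher ranks make NIPALS coefficients
    compete within a correlated band, so the coefficient — and hence the
    stability — of individual in-band frequencies becomes erratic, while
    a low-rank fit keeps coefficients close to aggregate covariances.

    Columns whose coefficients have zero variance across the LOO fits
    get stability 0 (with a warning) rather than an undefined ratio.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    noise = noise_scale * rng.random((n, p))
    augmented = np.hstack([X, noise])

    L = loo_coefficient_matrix(augmented, y, feasible_components(augmented, n_components))
    means = L.mean(axis=0)
    stds = L.std(axis=0)
    stability = np.zeros(2 * p)
    ok = stds > 0
    if not np.all(ok):
        warnings.warn(
            f"{np.sum(~ok)} column(s) with zero coefficient variance; stability set to 0",
            stacklevel=2,
        )
    stability[ok] = means[ok] / stds[ok]

    threshold = threshold_factor * np.max(np.abs(stability[p:]))
    selected = np.flatnonzero(np.abs(stability[:p]) > threshold)
    return UVEResult(
        stability=stability[:p],
        noise_stability=stability[p:],
        threshold=float(threshold),
        selected=selected,
    )


# ---------------------------------------------------------------------------
# SCARS


def edf_schedule(p: int, n_runs: int) -> np.ndarray:
    """Exponentially decaying retention ratios r_i = a e^{-k i}, i = 1..n_runs.

    Endpoints fix the constants: r_1 = (p-1)/p (essentially the full band)
    and r_{n_runs} = 2/p (two variables), the usual convention for
    competitive adaptive reweighted sampling schedules.
    """
    if p < 3:
        raise ValueError("need at least 3 variables for an EDF schedule")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    k = np.log((p - 1) / 2.0) / (n_runs - 1)
    a = ((p - 1) / p) * np.exp(k)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def _mc_stability(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_draws: int,
    mc_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """|mean| / sd of PLS coefficients over Monte-Carlo calibration subsamples."""
    n, p = X.shape
    m = max(2, int(round(mc_fraction * n)))
    B = np.empty((n_draws, p))
    for d in range(n_draws):
        rows = rng.choice(n, size=m, replace=False)
        a = feasible_components(X[rows], n_components)
        B[d] = _nipals_coef(X[rows], y[rows], a)
    sd = B.std(axis=0)
    c = np.zeros(p)
    ok = sd > 0
    c[ok] = np.abs(B.mean(axis=0)[ok]) / sd[ok]
    return c


def scars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 5,
    n_runs: int = 50,
    mc_fraction: float = 0.5,
    n_mc_draws: int = 50,
    n_folds: int = 10,
    seed: int = 0,
) -> SCARSResult:
    """Stability competitive adaptive reweighted sampling.

    Per run ``i`` (1-based) over the surviving variables:

    1. Monte-Carlo stability: ``n_mc_draws`` subsamples of
       ``mc_fraction`` of the calibration samples are fit by PLS and
       ``c_j = |mean(b_j)| / sd(b_j)`` summarizes each variable. The
       half-sized draws matter: draws sharing most of their samples keep
       chance correlations (e.g. interferents that happen to track
       nitrogen in this calibration set) looking stable, while half-size
       draws let them flip and be ranked down.
    2. Forced selection: half of the run's EDF quota ``r_i * P`` is
       filled deterministically with the top variables by ``c_j``.
    3. Adaptive reweighted sampling: the rest of the quota is drawn
       without replacement from the remaining surviving variables with
       probability proportional to ``c_j``, so subset sizes follow the
       decay schedule exactly (up to rounding) while weaker variables
       keep a stability-weighted chance of survival.
    4. The subset is scored by k-fold RMSECV (PLS components clipped to
       the subset size).

    The subset of the run with minimal RMSECV is returned. Deterministic
    given ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 0 < mc_fraction < 1:
        raise ValueError("mc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ratios = edf_schedule(p, n_runs)
    # one fold partition shared by every run: RMSECV differences between runs
    # then reflect the subsets, not fold-assignment luck
    cv_seed = int(rng.integers(2**31 - 1))

    surviving = np.arange(p)
    subsets: list[np.ndarray] = []
    rmsecvs = np.empty(n_runs)
    for i in range(n_runs):
        Xs = X[:, surviving]
        c = _mc_stability(Xs, y, n_components, n_mc_draws, mc_fraction, rng)

        n_keep = max(2, int(round(ratios[i] * p)))
        n_keep = min(n_keep, surviving.size)
        order = np.argsort(-c, kind="stable")  # ties break toward lower index
        n_forced = max(1, n_keep // 2)
        forced = order[:n_forced]
        pool = order[n_forced:]
        n_sample = min(n_keep - n_forced, pool.size)
        if n_sample > 0:
            weights = c[pool]
            if weights.sum() <= 0:
                weights = np.ones(pool.size)
            sampled = rng.choice(
                pool, size=n_sample, replace=False, p=weights / weights.sum()
            )
            local = np.concatenate([forced, sampled])
        else:
            local = forced
        subset = np.sort(surviving[local])

        folds = min(n_folds, n)
        cv = cross_validate(
            X[:, subset],
            y,
            feasible_components(X[:, subset], n_components),
            scheme="kfold",
            n_folds=folds,
            seed=cv_seed,
        )
        subsets.append(subset)
        rmsecvs[i] = cv.rmsecv
        surviving = subset

    best = int(np.argmin(rmsecvs))
    return SCARSResult(
        runs=n_runs,
        per_run_subsets=subsets,
        per_run_rmsecv=rmsecvs,
        best_run=best,
        selected=subsets[best],
    )


# ---------------------------------------------------------------------------
# iPLS


def _interval_blocks(p: int, n_intervals: int) -> list[np.ndarray]:
    """Contiguous index blocks tiling 0..p-1, sizes differing by at most 1."""
    return [np.asarray(b) for b in np.array_split(np.arange(p), n_intervals)]


def _interval_bounds(freq_max: float, n_intervals: int) -> list[tuple[float, float]]:
    """Nominal THz bounds of each interval, labeled with a 4-decimal width.

    The interval width is rounded to 4 decimals before multiplying out
    the boundaries, reproducing the conventional printed interval tables
    of chemometrics software (e.g. 1.4/22 -> 0.0636, interval 12 ->
    0.6996-0.7632); the final upper bound is capped at the true band edge.
    """
    w = round(freq_max / n_intervals, 4)
    bounds = []
    for i in range(n_intervals):
        lo = round(i * w, 4)
        hi = round((i + 1) * w, 4) if i < n_intervals - 1 else freq_max
        bounds.append((lo, hi))
    return bounds


def ipls_select(
    X: np.ndarray,
    y: np.ndarray,
    frequencies: np.ndarray,
    n_intervals: int,
    n_components: int = 5,
) -> IPLSResult:
    """Interval PLS: keep the equidistant grid interval whose local model
    cross-validates best (leave-one-out RMSECV)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    frequencies = np.asarray(frequencies, dtype=float)
    p = X.shape[1]
    if frequencies.size != p:
        raise ValueError("frequency grid length must match the number of variables")
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    if n_intervals > p:
        raise ValueError("more intervals than variables")

    blocks = _interval_blocks(p, n_intervals)
    rmsecvs = np.empty(n_intervals)
    for i, block in enumerate(blocks):
        a = feasible_components(X[:, block], n_components)
        rmsecvs[i] = cross_validate(X[:, block], y, a, scheme="loo").rmsecv
    best = int(np.argmin(rmsecvs))
    return IPLSResult(
        n_intervals=n_intervals,
        interval_bounds_thz=_interval_bounds(float(frequencies[-1]), n_intervals),
        interval_indices=blocks,
        per_interval_rmsecv=rmsecvs,
        best_interval=best,
        selected=blocks[best],
    )


def ipls_interval_search(
    X: np.ndarray,
    y: np.ndarray,
    frequencies: np.ndarray,
    candidate_range: tuple[int, int] = (10, 45),
    n_components: int = 5,
) -> tuple[int, np.ndarray]:
    """Search the interval count: best RMSECV attained by ipls_select per candidate n.

    Returns (argmin n, trace of best-interval RMSECV per candidate,
    indexed in candidate order).
    """
    lo, hi = candidate_range
    if lo > hi:
        raise ValueError("empty candidate range")
    if lo < 2:
        raise ValueError("interval counts below 2 are not meaningful")
    candidates = range(lo, hi + 1)
    trace = np.empty(len(candidates))
    for k, n_int in enumerate(candidates):
        res = ipls_select(X, y, frequencies, n_int, n_components)
        trace[k] = res.per_interval_rmsecv[res.best_interval]
    best_n = int(lo + np.argmin(trace))
    return best_n, trace
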