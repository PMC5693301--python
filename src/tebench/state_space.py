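"""Delay-embedding reconstruction and Ragwitz-criterion optimization.

The embedding dimension d and delay tau of each channel are chosen by
minimizing the one-step root-mean-squared prediction error (RMSPE) of a
local constant (nearest-neighbor-mean) predictor over a grid of d = 1..9
and tau = {0.1, ..., 1.0} x ACT, where the ACT (autocorrelation decay
time) is the smallest lag at which the autocorrelation drops to 1/e.
Temporal neighbors within a Theiler window are excluded from all
neighbor searches to avoid serial-correlation bias.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["EmbeddingParams", "act", "act_ensemble", "embed",
           "local_constant_predict", "rmspe", "optimize_embedding",
           "DegenerateSeriesError", "DEFAULT_D_RANGE", "DEFAULT_TAU_FACTORS"]

DEFAULT_D_RANGE = tuple(range(1, 10))
DEFAULT_TAU_FACTORS = tuple(round(0.1 * i, 1) for i in range(1, 11))


class DegenerateSeriesError(ValueError):
    """Raised for inputs on which the operation is undefined (e.g. a
    constant series, whose autocorrelation does not exist)."""


@dataclasses.dataclass(frozen=True)
class EmbeddingParams:
    """Per-channel state-space reconstruction parameters."""

    d: int
    tau: int
    act: int
    rmspe: float

    def __post_init__(self) -> None:
        if self.d < 1 or self.tau < 1 or self.act < 1:
            raise ValueError("d, tau and act must all be >= 1")


def act(series: np.ndarray, max_lag: int | None = None) -> int:
    """Autocorrelation decay time: smallest positive lag at which the
    normalized autocorrelation drops to <= 1/e.

    If the autocorrelation never crosses 1/e within ``max_lag`` (default
    n - 1) the search bound is returned with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        raise DegenerateSeriesError("autocorrelation undefined for a "
                                    "constant series")
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    # biased autocorrelation via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    r = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1] / denom
    below = np.nonzero(r[1:] <= 1.0 / np.e)[0]
    if below.size == 0:
        warnings.warn("autocorrelation did not decay to 1/e within "
                      f"{max_lag} lags; returning the bound", stacklevel=2)
        return max_lag
    return int(below[0]) + 1


def act_ensemble(trials: np.ndarray, max_lag: int | None = None) -> int:
    """Aggregate per-trial ACTs of one channel by their maximum."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    return max(act(tr, max_lag=max_lag) for tr in trials)


def embed(series: np.ndarray, d: int, tau: int) -> np.ndarray:
    """Takens delay embedding.

    Returns an ``(n - (d-1)*tau, d)`` array whose row ``i`` is
    ``[x[i], x[i+tau], ..., x[i+(d-1)*tau]]``, i.e. the state vector
    whose most recent sample is ``x[i + (d-1)*tau]``.
    """
    x = np.asarray(series, dtype=float)
    if d < 1 or tau < 1:
        raise ValueError("d and tau must be >= 1")
    m = x.size - (d - 1) * tau
    if m <= 0:
        raise ValueError("series too short for the requested embedding")
    idx = np.arange(m)[:, None] + np.arange(d)[None, :] * tau
    return x[idx]


def rmspe(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Root mean squared componentwise prediction error."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("predicted and actual must have the same shape")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def _knn_indices(states: np.ndarray, k: int, theiler: int,
                 query_idx: np.ndarray | None = None) -> np.ndarray:
    """Indices of the k nearest states (max-norm) for every queried
    state, with self-matches and temporal neighbors within ``theiler``
    excluded.  Neighbors are always drawn from all of ``states``;
    ``query_idx`` restricts which states are queried."""
    n = states.shape[0]
    if n <= k + 1:
        raise ValueError("not enough state vectors for k neighbors")
    if query_idx is None:
        query_idx = np.arange(n)
    tree = cKDTree(states)
    q = min(n, k + 2 * theiler + 1)
    _dist, idx = tree.query(states[query_idx], k=q, p=np.inf)
    if q == 1:
        idx = idx[:, None]
    valid = np.abs(idx - query_idx[:, None]) > theiler
    out = np.empty((len(query_idx), k), dtype=np.intp)
    short = []
    for row, i in enumerate(query_idx):
        good = idx[row][valid[row]]
        if good.size >= k:
            out[row] = good[:k]
        else:
            short.append((row, i))
    if short:
        # brute-force fallback for rows whose window exclusions crowded
        # out the capped query
        for row, i in short:
            dist_all = np.max(np.abs(states - states[i]), axis=1)
            dist_all[max(0, i - theiler): i + theiler + 1] = np.inf
            if np.sum(np.isfinite(dist_all)) < k:
                raise ValueError("too few admissible neighbors after "
                                 "Theiler exclusion")
            out[row] = np.argsort(dist_all, kind="stable")[:k]
    return out


def local_constant_predict(series: np.ndarray, d: int, tau: int,
                           k_neighbors: int = 4, horizon: int = 1,
                           theiler: int = 0,
                           max_points: int | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Local constant (zeroth-order) state predictor.

    Each state's prediction ``horizon`` steps ahead is the mean of its
    ``k_neighbors`` nearest states' successors (max-norm metric), with
    the state itself and temporal neighbors within ``theiler`` samples
    excluded.  Returns ``(predicted, actual)`` successor-state arrays.

    ``max_points`` caps the number of (evenly spaced) states that are
    predicted; neighbors are still drawn from all states.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    states = embed(series, d, tau)
    m = states.shape[0] - horizon
    if m <= k_neighbors:
        raise ValueError("series too short for prediction with k neighbors")
    base = states[:m]  # states that have a successor
    if max_points is not None and max_points < m:
        query_idx = np.unique(
            np.round(np.linspace(0, m - 1, max_points)).astype(np.intp))
    else:
        query_idx = np.arange(m)
    nn = _knn_indices(base, k_neighbors, theiler, query_idx=query_idx)
    predicted = states[nn + horizon].mean(axis=1)
    actual = states[query_idx + horizon]
    return predicted, actual


def optimize_embedding(trials: np.ndarray,
                       act_value: int | None = None,
                       d_range: Iterable[int] = DEFAULT_D_RANGE,
                       tau_factors: Sequence[float] = DEFAULT_TAU_FACTORS,
                       k_neighbors: int = 4,
                       theiler: int | None = None,
                       horizon: int = 1,
                       max_points: int | None = None) -> EmbeddingParams:
    """Exhaustive Ragwitz grid search for one channel.

    ``trials`` is ``(n_trials, n)`` (or 1-D for a single trial).  For
    each (d, tau) pair the one-step RMSPE of the newly predicted sample
    (the most recent state component — the only component not pinned by
    the neighborhood radius itself) is pooled over trials; the pair
    attaining the grid minimum wins, with ties broken toward smaller d,
    then smaller tau.  ``max_points`` caps predicted states per trial
    for large grids.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if act_value is None:
        act_value = act_ensemble(trials)
    if theiler is None:
        theiler = act_value
    taus = sorted({max(1, int(round(f * act_value))) for f in tau_factors})
    best: tuple[float, int, int] | None = None
    for d in d_range:
        for tau in taus:
            sq_sum = 0.0
            n_obs = 0
            try:
                for tr in trials:
                    pred, actual = local_constant_predict(
                        tr, d, tau, k_neighbors=k_neighbors,
                        horizon=horizon, theiler=theiler,
                        max_points=max_points)
                    err1 = pred[:, -1] - actual[:, -1]
                    sq_sum += float(err1 @ err1)
                    n_obs += err1.size
            except ValueError:
                continue  # grid point infeasible for this trial length
            err = np.sqrt(sq_sum / n_obs)
            if best is None or err < best[0]:
                best = (err, d, tau)
    if best is None:
        raise ValueError("no feasible (d, tau) grid point for these trials")
    err, d, tau = best
    return EmbeddingParams(d=d, tau=tau, act=act_value, rmspe=err)
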