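"""Nearest-neighbor (KSG-style) transfer-entropy estimation.

Transfer entropy from a source X to a target Y is the conditional mutual
information I(X_past; Y_present | Y_past).  The estimator here is the
self-prediction-optimized (SPO) variant: for each admissible time t it
forms the triple

    ( y_t , y-state ending at t-1 , x-state ending at t-u )

with per-channel delay embeddings, finds each triple's k-th nearest
neighbor in the joint space under the max-norm, and converts strict
neighbor counts within that distance in three marginal subspaces into
digamma terms:

    TE = psi(k) + < psi(n_ypast + 1) - psi(n_{y,ypast} + 1)
                                     - psi(n_{ypast,xpast} + 1) >

Values are in nats (natural-log units) and may be slightly negative for
near-independent data due to estimator bias.  Temporal neighbors within
a Theiler window are excluded from the k-th-neighbor search and from all
marginal counts.  Scanning the candidate interaction delay u and taking
the argmax of the trial-averaged TE reconstructs the coupling delay.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .state_space import EmbeddingParams, embed

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = ["TEConfig", "TEScanResult", "te_spo", "scan_delays",
           "InsufficientDataError", "NATS_TO_BITS"]

NATS_TO_BITS = 1.0 / np.log(2.0)


class InsufficientDataError(ValueError):
    """Raised when too few joint points remain after embedding/trimming."""


@dataclasses.dataclass(frozen=True)
class TEConfig:
    """Estimator settings.

    ``k`` nearest neighbors are found in the joint (highest-dimensional)
    space; the max-norm metric is used throughout.  ``theiler_window``
    excludes serially correlated points from all neighbor operations.
    ``jitter`` is the relative amplitude of seeded uniform noise added to
    the series before estimation to break distance ties on discretized
    or filtered data (reproducible via ``jitter_seed``).
    """

    k: int = 4
    u_range: tuple[int, ...] = tuple(range(1, 11))
    theiler_window: int = 1
    jitter: float = 1e-8
    jitter_seed: int = 0
    backend: str = "direct"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.u_range) == 0 or min(self.u_range) < 1:
            raise ValueError("u_range must be nonempty and positive")
        if self.theiler_window < 0:
            raise ValueError("theiler_window must be >= 0")
        if self.backend not in ("direct", "kdtree"):
            raise ValueError("backend must be 'direct' or 'kdtree'")


@dataclasses.dataclass
class TEScanResult:
    """TE as a function of candidate interaction delay u.

    ``per_trial_te`` has shape ``(n_u, n_trials)``; ``te_by_u`` is its
    trial mean.  ``u_star`` is the delay maximizing the trial-mean TE
    (ties broken toward smaller u).
    """

    u_values: tuple[int, ...]
    per_trial_te: np.ndarray
    u_star: int
    emb_source: EmbeddingParams
    emb_target: EmbeddingParams

    @property
    def te_by_u(self) -> np.ndarray:
        return self.per_trial_te.mean(axis=1)

    @property
    def te_at_u_star(self) -> np.ndarray:
        """Per-trial TE at the selected delay."""
        return self.per_trial_te[self.u_values.index(self.u_star)]


def _jittered(x: np.ndarray, amplitude: float,
              rng: np.random.Generator) -> np.ndarray:
    if amplitude <= 0:
        return x
    sd = x.std()
    if sd == 0:
        sd = 1.0
    return x + rng.uniform(-1.0, 1.0, x.shape) * amplitude * sd


def _strict_counts(pts: np.ndarray, radii: np.ndarray,
                   theiler: int) -> np.ndarray:
    """For each point i, the number of other points j with
    max-norm distance strictly below ``radii[i]`` and |i - j| > theiler.

    Distances that tie ``radii[i]`` exactly (the joint k-th neighbor's
    projection when its largest coordinate lies in this subspace) are
    excluded by shrinking the query radius by one ULP; with the tie-break
    jitter applied upstream no other distance can fall in that gap.
    """
    tree = cKDTree(pts)
    r = np.nextafter(radii, 0.0)
    counts = np.asarray(
        tree.query_ball_point(pts, r, p=np.inf, return_length=True),
        dtype=np.int64)
    counts -= 1  # self (distance 0)
    n = pts.shape[0]
    for off in range(1, theiler + 1):
        if off >= n:
            break
        d_off = np.max(np.abs(pts[:-off] - pts[off:]), axis=1)
        counts[:-off] -= d_off <= r[:-off]
        counts[off:] -= d_off <= r[off:]
    return counts


def _kth_distances(joint: np.ndarray, k: int, theiler: int) -> np.ndarray:
    """Max-norm distance to the k-th nearest neighbor of every joint
    point, excluding self and Theiler-window neighbors."""
    n = joint.shape[0]
    tree = cKDTree(joint)
    q = min(n, k + 2 * theiler + 1)
    dist, idx = tree.query(joint, k=q, p=np.inf)
    if q == 1:
        dist, idx = dist[:, None], idx[:, None]
    rows = np.arange(n)[:, None]
    valid = np.abs(idx - rows) > theiler
    cum = np.cumsum(valid, axis=1)
    has_k = cum[:, -1] >= k
    pos = np.argmax(cum == k, axis=1)
    eps = dist[np.arange(n), pos]
    for i in np.nonzero(~has_k)[0]:
        d_all = np.max(np.abs(joint - joint[i]), axis=1)
        d_all[max(0, i - theiler): i + theiler + 1] = np.inf
        finite = np.sort(d_all[np.isfinite(d_all)], kind="stable")
        if finite.size < k:
            raise InsufficientDataError(
                "fewer than k admissible neighbors after Theiler exclusion")
        eps[i] = finite[k - 1]
    return eps


@njit(cache=True)
def _direct_counts(y_now: np.ndarray, y_past: np.ndarray,
                   x_past: np.ndarray, k: int, theiler: int):
    """All-pairs max-norm neighbor statistics in one fused pass.

    For every joint point: the distance to its k-th nearest neighbor
    (self and Theiler-window neighbors excluded) and the strict neighbor
    counts within that distance in the three marginal subspaces.  The
    joint distance is the max of the marginal component distances, so
    the coordinate loops bail out as soon as the running maximum
    exceeds the current bound.
    """
    n = y_now.shape[0]
    dy = y_past.shape[1]
    dx = x_past.shape[1]
    eps = np.empty(n)
    n1 = np.zeros(n, np.int64)
    n2 = np.zeros(n, np.int64)
    n3 = np.zeros(n, np.int64)
    kd = np.empty(k)
    for i in range(n):
        m = 0
        bound = np.inf  # current k-th distance; lets the coord loop bail
        for j in range(n):
            if abs(i - j) <= theiler:
                continue
            d = abs(y_now[i] - y_now[j])
            if d < bound:
                for c in range(dy):
                    v = abs(y_past[i, c] - y_past[j, c])
                    if v > d:
                        d = v
                        if d >= bound:
                            break
            if d < bound:
                for c in range(dx):
                    v = abs(x_past[i, c] - x_past[j, c])
                    if v > d:
                        d = v
                        if d >= bound:
                            break
            if d >= bound:
                continue
            if m < k:
                kd[m] = d
                m += 1
                if m == k:  # sort the initial k ascending
                    for a in range(1, k):
                        key = kd[a]
                        b = a - 1
                        while b >= 0 and kd[b] > key:
                            kd[b + 1] = kd[b]
                            b -= 1
                        kd[b + 1] = key
                    bound = kd[k - 1]
            else:
                b = k - 2
                while b >= 0 and kd[b] > d:
                    kd[b + 1] = kd[b]
                    b -= 1
                kd[b + 1] = d
                bound = kd[k - 1]
        if m < k:
            eps[i] = -1.0  # sentinel: too few admissible neighbors
            continue
        e = kd[k - 1]
        eps[i] = e
        c1 = 0
        c2 = 0
        c3 = 0
        for j in range(n):
            if abs(i - j) <= theiler:
                continue
            dyp = 0.0
            for c in range(dy):
                v = abs(y_past[i, c] - y_past[j, c])
                if v > dyp:
                    dyp = v
                    if dyp >= e:
                        break
            if dyp >= e:
                continue  # every marginal containing y_past is >= dyp
            c1 += 1
            dn = abs(y_now[i] - y_now[j])
            if dn < e:
                c2 += 1
            dxp = 0.0
            for c in range(dx):
                v = abs(x_past[i, c] - x_past[j, c])
                if v > dxp:
                    dxp = v
                    if dxp >= e:
                        break
            if dxp < e:
                c3 += 1
        n1[i] = c1
        n2[i] = c2
        n3[i] = c3
    return eps, n1, n2, n3


def _te_single(x: np.ndarray, y: np.ndarray, emb_src: EmbeddingParams,
               emb_tgt: EmbeddingParams, u: int, config: TEConfig,
               rng: np.random.Generator) -> float:
    n = y.size
    dx, tx = emb_src.d, emb_src.tau
    dy, ty = emb_tgt.d, emb_tgt.tau
    x = _jittered(np.asarray(x, dtype=float), config.jitter, rng)
    y = _jittered(np.asarray(y, dtype=float), config.jitter, rng)
    # earliest t for which both the target state at t-1 and the source
    # state at t-u are fully inside the series
    t0 = max(1 + (dy - 1) * ty, u + (dx - 1) * tx)
    t = np.arange(t0, n)
    if t.size <= config.k + 2 * config.theiler_window + 1:
        raise InsufficientDataError("too few joint points after trimming")
    y_states = embed(y, dy, ty)   # row i ends at sample i + (dy-1)*ty
    x_states = embed(x, dx, tx)
    y_now = y[t][:, None]
    y_past = y_states[t - 1 - (dy - 1) * ty]
    x_past = x_states[t - u - (dx - 1) * tx]

    if config.backend == "direct" and _HAVE_NUMBA:
        eps, n1, n2, n3 = _direct_counts(
            np.ascontiguousarray(y_now[:, 0]),
            np.ascontiguousarray(y_past),
            np.ascontiguousarray(x_past),
            config.k, config.theiler_window)
        if np.any(eps < 0):
            raise InsufficientDataError(
                "fewer than k admissible neighbors after Theiler exclusion")
    else:
        joint = np.hstack([y_now, y_past, x_past])
        eps = _kth_distances(joint, config.k, config.theiler_window)
        n1 = _strict_counts(y_past, eps, config.theiler_window)
        n2 = _strict_counts(np.hstack([y_now, y_past]), eps,
                            config.theiler_window)
        n3 = _strict_counts(np.hstack([y_past, x_past]), eps,
                            config.theiler_window)
    return float(digamma(config.k)
                 + np.mean(digamma(n1 + 1) - digamma(n2 + 1)
                           - digamma(n3 + 1)))


def te_spo(source, target, emb_src: EmbeddingParams,
           emb_tgt: EmbeddingParams, u: int, config: TEConfig,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-trial SPO transfer entropy (nats) at candidate delay ``u``.

    ``source`` and ``target`` are ``(n_trials, n)`` arrays (1-D inputs
    are treated as a single trial).
    """
    if u < 1:
        raise ValueError("u must be >= 1")
    src = np.atleast_2d(np.asarray(source, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != tgt.shape:
        raise ValueError("source and target must have matching shapes")
    if rng is None:
        rng = np.random.default_rng(config.jitter_seed)
    return np.array([
        _te_single(src[i], tgt[i], emb_src, emb_tgt, u, config, rng)
        for i in range(src.shape[0])
    ])


def scan_delays(source, target, emb_src: EmbeddingParams,
                emb_tgt: EmbeddingParams, config: TEConfig,
                rng: np.random.Generator | None = None) -> TEScanResult:
    """Evaluate TE at every candidate delay in ``config.u_range`` and
    select the delay maximizing the trial-mean TE."""
    if rng is None:
        rng = np.random.default_rng(config.jitter_seed)
    per_trial = np.stack([
        te_spo(source, target, emb_src, emb_tgt, u, config, rng)
        for u in config.u_range
    ])
    means = per_trial.mean(axis=1)
    u_star = int(config.u_range[int(np.argmax(means))])  # first max: small u
    return TEScanResult(u_values=tuple(config.u_range),
                        per_trial_te=per_trial, u_star=u_star,
                        emb_source=emb_src, emb_target=emb_tgt)
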