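"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's neighbor-search code paths: all
pairwise distances are materialized with plain numpy and counts are
taken by explicit comparison, so they serve as an oracle for the
estimator's neighbor conventions (max-norm, Theiler exclusion, strict
counts within the k-th joint neighbor distance).
"""

import numpy as np
from scipy.special import digamma


def embed_oracle(x, d, tau):
    n = len(x)
    m = n - (d - 1) * tau
    return np.array([[x[i + j * tau] for j in range(d)] for i in range(m)])


def brute_te_counts(y_now, y_past, x_past, k, theiler):
    """Per-point (eps, n1, n2, n3) by explicit all-pairs distances."""
    n = len(y_now)
    joint = np.hstack([y_now[:, None], y_past, x_past])
    yy = np.hstack([y_now[:, None], y_past])
    yx = np.hstack([y_past, x_past])
    eps = np.empty(n)
    n1 = np.empty(n, dtype=int)
    n2 = np.empty(n, dtype=int)
    n3 = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.abs(np.arange(n) - i) > theiler
        d_joint = np.max(np.abs(joint - joint[i]), axis=1)
        eps[i] = np.sort(d_joint[mask])[k - 1]
        d1 = np.max(np.abs(y_past - y_past[i]), axis=1)
        d2 = np.max(np.abs(yy - yy[i]), axis=1)
        d3 = np.max(np.abs(yx - yx[i]), axis=1)
        n1[i] = np.sum(mask & (d1 < eps[i]))
        n2[i] = np.sum(mask & (d2 < eps[i]))
        n3[i] = np.sum(mask & (d3 < eps[i]))
    return eps, n1, n2, n3


def brute_te(x, y, d_x, tau_x, d_y, tau_y, u, k, theiler):
    """Brute-force SPO transfer entropy (nats) on one trial."""
    n = len(y)
    t0 = max(1 + (d_y - 1) * tau_y, u + (d_x - 1) * tau_x)
    t = np.arange(t0, n)
    ys = embed_oracle(y, d_y, tau_y)
    xs = embed_oracle(x, d_x, tau_x)
    y_now = y[t]
    y_past = ys[t - 1 - (d_y - 1) * tau_y]
    x_past = xs[t - u - (d_x - 1) * tau_x]
    _eps, n1, n2, n3 = brute_te_counts(y_now, y_past, x_past, k, theiler)
    return float(digamma(k)
                 + np.mean(digamma(n1 + 1) - digamma(n2 + 1)
                           - digamma(n3 + 1)))


def brute_local_predict(series, d, tau, k, horizon, theiler):
    """Brute-force local constant predictor (all-pairs distances)."""
    states = embed_oracle(series, d, tau)
    m = len(states) - horizon
    base = states[:m]
    pred = np.empty((m, d))
    for i in range(m):
        dist = np.max(np.abs(base - base[i]), axis=1)
        dist[max(0, i - theiler): i + theiler + 1] = np.inf
        nn = np.argsort(dist, kind="stable")[:k]
        pred[i] = states[nn + horizon].mean(axis=0)
    return pred, states[horizon: horizon + m]
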