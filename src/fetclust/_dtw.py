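"""Numba kernels for dynamic time warping and barycenter averaging.

The recurrence is the classic unconstrained one,

    gamma(i, j) = d(q_i, c_j) + min(gamma(i-1, j-1), gamma(i-1, j), gamma(i, j-1))

with boundary gamma(1, 1) = d(q_1, c_1) and no warping-window constraint.
The local cost is |q_i - c_j| by default; ``squared`` switches to
(q_i - c_j)^2.  These kernels are the hot path of k-means training, so
they are jitted; the public wrappers live in :mod:`fetclust.tac`.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _local(a, b, squared):
    d = a - b
    if d < 0.0:
        d = -d
    if squared:
        d = d * d
    return d


@njit(cache=False)
def dtw_cost(q, c, squared):
    """Cumulative DTW cost gamma(n, m) in O(m) memory."""
    n = q.shape[0]
    m = c.shape[0]
    prev = np.empty(m)
    curr = np.empty(m)
    prev[0] = _local(q[0], c[0], squared)
    for j in range(1, m):
        prev[j] = prev[j - 1] + _local(q[0], c[j], squared)
    for i in range(1, n):
        curr[0] = prev[0] + _local(q[i], c[0], squared)
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = best + _local(q[i], c[j], squared)
        for j in range(m):
            prev[j] = curr[j]
    return prev[m - 1]


@njit(cache=False)
def _dtw_gamma(q, c, squared):
    n = q.shape[0]
    m = c.shape[0]
    g = np.empty((n, m))
    g[0, 0] = _local(q[0], c[0], squared)
    for j in range(1, m):
        g[0, j] = g[0, j - 1] + _local(q[0], c[j], squared)
    for i in range(1, n):
        g[i, 0] = g[i - 1, 0] + _local(q[i], c[0], squared)
        for j in range(1, m):
            best = g[i - 1, j - 1]
            if g[i - 1, j] < best:
                best = g[i - 1, j]
            if g[i, j - 1] < best:
                best = g[i, j - 1]
            g[i, j] = best + _local(q[i], c[j], squared)
    return g


@njit(cache=False)
def dtw_path(q, c, squared):
    """Optimal warping path as an (L, 2) array of (i, j) pairs.

    Backtracks from (n-1, m-1) preferring the diagonal predecessor on
    ties so the path is deterministic.
    """
    g = _dtw_gamma(q, c, squared)
    n = q.shape[0]
    m = c.shape[0]
    path = np.empty((n + m - 1, 2), dtype=np.int64)
    L = 0
    i = n - 1
    j = m - 1
    path[L, 0] = i
    path[L, 1] = j
    L += 1
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag = g[i - 1, j - 1]
            up = g[i - 1, j]
            left = g[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        path[L, 0] = i
        path[L, 1] = j
        L += 1
    return path[:L][::-1]


@njit(cache=False)
def dtw_assign(X, C, squared):
    """Nearest centroid (by DTW cost) for each row of X."""
    V = X.shape[0]
    k = C.shape[0]
    labels = np.empty(V, dtype=np.int64)
    dists = np.empty(V)
    for v in range(V):
        best = np.inf
        bi = 0
        for j in range(k):
            d = dtw_cost(X[v], C[j], squared)
            if d < best:
                best = d
                bi = j
        labels[v] = bi
        dists[v] = best
    return labels, dists


@njit(cache=False)
def dba_update(X, labels, C, n_inner, squared, tol):
    """One k-means centroid update via DTW barycenter averaging.

    For every cluster, repeatedly align each member series to the current
    centroid and replace each centroid sample by the mean of the member
    samples warped onto it, until the centroid moves less than ``tol`` or
    ``n_inner`` passes have run.  Empty clusters keep their centroid.
    """
    k = C.shape[0]
    T = C.shape[1]
    newC = C.copy()
    for ci in range(k):
        members = np.flatnonzero(labels == ci)
        if members.size == 0:
            continue
        cent = newC[ci].copy()
        for _ in range(n_inner):
            s = np.zeros(T)
            cnt = np.zeros(T)
            for vi in members:
                path = dtw_path(X[vi], cent, squared)
                for p in range(path.shape[0]):
                    s[path[p, 1]] += X[vi, path[p, 0]]
                    cnt[path[p, 1]] += 1.0
            moved = 0.0
            for t in range(T):
                upd = s[t] / cnt[t]
                d = upd - cent[t]
                if d < 0.0:
                    d = -d
                if d > moved:
                    moved = d
                cent[t] = upd
            if moved < tol:
                break
        newC[ci] = cent
    return newC
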