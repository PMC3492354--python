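"""Independent brute-force oracles used by the test suite.

Deliberately written with explicit Python loops and statistics-module
arithmetic so they share no code path with the vectorized
implementations they check.
"""

import itertools
import math
import statistics

import numpy as np

T_SENTINEL = 1e12


def pooled_t(a, b):
    na, nb = len(a), len(b)
    va = statistics.variance(a)
    vb = statistics.variance(b)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0:
        diff = statistics.mean(a) - statistics.mean(b)
        return 0.0 if diff == 0 else math.copysign(T_SENTINEL, diff)
    return (statistics.mean(a) - statistics.mean(b)) / math.sqrt(
        sp2 * (1 / na + 1 / nb)
    )


def brute_force_maxt(X, n_a):
    """Free step-down maxT by explicit enumeration of all label splits."""
    X = [list(row) for row in X]
    m = len(X)
    n = len(X[0])
    splits = list(itertools.combinations(range(n), n_a))
    obs = tuple(range(n_a))

    def tval(row, combo):
        a = [row[i] for i in combo]
        b = [row[i] for i in range(n) if i not in combo]
        return abs(pooled_t(a, b))

    t_obs = [tval(row, obs) for row in X]
    order = sorted(range(m), key=lambda i: -t_obs[i])
    p_raw = []
    for i in range(m):
        count = sum(1 for c in splits if tval(X[i], c) >= t_obs[i])
        p_raw.append(count / len(splits))
    counts = [0] * m
    for c in splits:
        u = 0.0
        umax = [0.0] * m
        for pos in range(m - 1, -1, -1):
            u = max(u, tval(X[order[pos]], c))
            umax[pos] = u
        for pos in range(m):
            if umax[pos] >= t_obs[order[pos]]:
                counts[pos] += 1
    p_sorted = [c / len(splits) for c in counts]
    for pos in range(1, m):
        p_sorted[pos] = max(p_sorted[pos], p_sorted[pos - 1])
    p_adj = [0.0] * m
    for pos, i in enumerate(order):
        p_adj[i] = p_sorted[pos]
    return np.array(t_obs), np.array(p_raw), np.array(p_adj)


def bh_by_hand(p):
    """Direct O(m^2) evaluation of q_i = min_{p_j >= p_i} p_j * m / j."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    sorted_p = np.asarray(p)[order]
    for i in range(m):
        q[order[i]] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    return q


def hypergeom_tail_by_enumeration(k, n, K, N):
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(max(k, n + K - N), min(n, K) + 1)
    ) / total
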