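"""Independent brute-force oracles used to validate the pipeline's numerics.

Everything here is deliberately naive (enumeration, Fractions, all-pairs
path listing) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, sqrt

import numpy as np


def bh_stepup(p):
    """Step-up BH: adj(i) = min_{j >= i} p_(j) * n / j, capped at 1."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def pooled_t(x, y):
    """Textbook equal-variance two-sample t: returns (logfc, t, df)."""
    x, y = list(map(float, x)), list(map(float, y))
    n1, n2 = len(x), len(y)
    mx = sum(x) / n1
    my = sum(y) / n2
    v1 = sum((a - mx) ** 2 for a in x) / (n1 - 1)
    v2 = sum((a - my) ** 2 for a in y) / (n2 - 1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    t = (my - mx) / sqrt(s2 * (1 / n1 + 1 / n2))
    return my - mx, t, df


def hypergeom_upper_tail(k, n, K, N):
    """Exact P(X >= k) by Fraction enumeration over the support."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(min(total, Fraction(1)))


def betweenness_by_enumeration(adj):
    """Unnormalized betweenness by listing *all* shortest paths.

    ``adj``: dict node -> set of neighbours (undirected).  Returns dict
    node -> sum over unordered source-target pairs (s != t, both != v) of
    the fraction of s-t shortest paths passing through v.
    """
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}

    def all_shortest_paths(s, t):
        # BFS to get distance, then DFS over predecessor structure
        from collections import deque

        dist = {s: 0}
        dq = deque([s])
        while dq:
            u = dq.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    dq.append(w)
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for w in adj[u]:
                if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                    path.append(w)
                    extend(path)
                    path.pop()

        extend([s])
        return [p for p in paths if p[-1] == t]

    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def knee_by_enumeration(x, y):
    """Max perpendicular chord distance after min-max scaling, brute force."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xs = (x - x.min()) / (x.max() - x.min())
    ys = (y - y.min()) / (y.max() - y.min())
    x0, y0, x1, y1 = xs[0], ys[0], xs[-1], ys[-1]
    denom = sqrt((x1 - x0) ** 2 + (y1 - y0) ** 2)
    best, best_i = -1.0, None
    for i in range(1, len(xs) - 1):
        d = abs((x1 - x0) * (ys[i] - y0) - (y1 - y0) * (xs[i] - x0)) / denom
        if d > best + 1e-12:
            best, best_i = d, i
    return int(x[best_i]), best
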