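"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive path enumeration,
combinatorial sums, sort-and-compare filters — and shares no code with the
package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math
from itertools import combinations
from statistics import median


def all_simple_paths(adj: dict, s, t) -> list[list]:
    """Every simple s-t path by depth-first enumeration."""
    paths, stack = [], [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nb in adj[node]:
            if nb not in path:
                stack.append((nb, path + [nb]))
    return paths


def brute_betweenness(nodes, edges) -> dict:
    """Unordered pair-fraction betweenness via exhaustive path enumeration."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    btw = {n: 0.0 for n in nodes}
    for s, t in combinations(sorted(nodes), 2):
        paths = all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            btw[v] += through / len(geodesics)
    return btw


def brute_distances(adj: dict, s) -> dict:
    """Plain breadth-first distances from s."""
    dist, frontier, d = {s: 0}, [s], 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_closeness(nodes, edges) -> dict:
    """Per-component closeness: (n_comp - 1) / sum of distances; isolated 0."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for v in nodes:
        dist = brute_distances(adj, v)
        total = sum(d for u, d in dist.items() if u != v)
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def brute_hub_filter(records: list[dict]) -> list[str]:
    """Sort-median-compare hub screen over topology records."""
    meds = {
        m: median(r[m] for r in records)
        for m in ("degree", "betweenness", "closeness")
    }
    return sorted(
        r["node_id"]
        for r in records
        if all(r[m] > meds[m] for m in meds)
    )


def hypergeom_tail_comb(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] as an explicit sum of binomial-coefficient ratios."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(n, K) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def hypergeom_tail_enumerate(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] by enumerating every n-subset of an N-element universe."""
    universe = list(range(N))
    special = set(range(K))
    hits = sum(
        1 for draw in combinations(universe, n)
        if len(special.intersection(draw)) >= k
    )
    return hits / math.comb(N, n)


def t_test_p_closed_form(values: list[float]) -> float:
    """Two-sided one-sample t p-value from the textbook statistic."""
    from scipy.stats import t as t_dist

    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    t_stat = mean / math.sqrt(var / n)
    return 2.0 * t_dist.sf(abs(t_stat), df=n - 1)
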