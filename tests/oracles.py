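"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — explicit BFS, exhaustive shortest-path
enumeration, exhaustive search over set partitions — kept free of the
package's own code paths and of networkx's algorithms so they can certify
them.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb

import numpy as np


def adjacency(edges, nodes):
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths(adj, dist_s, s, t):
    """Every shortest s->t path, by depth-limited enumeration."""
    target_len = dist_s[t]
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        if len(path) - 1 >= target_len:
            return
        for v in adj[u]:
            if v not in path and v in dist_s and dist_s[v] == len(path):
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_graph_metrics(edges, nodes):
    """Degree, unnormalized closeness/betweenness, diameter, avg path length.

    Closeness is 1 / (sum of distances within the node's component), 0 for
    isolated nodes. Betweenness counts each unordered pair once. Diameter
    and average path length are over connected pairs; None with no edges.
    """
    nodes = sorted(nodes)
    adj = adjacency(edges, nodes)
    dist = {u: bfs_distances(adj, u) for u in nodes}
    degree = {u: len(adj[u]) for u in nodes}
    closeness = {}
    for u in nodes:
        total = sum(d for v, d in dist[u].items() if v != u)
        closeness[u] = 1.0 / total if total > 0 else 0.0
    betweenness = {u: 0.0 for u in nodes}
    pair_d = []
    for s, t in combinations(nodes, 2):
        if t not in dist[s]:
            continue
        pair_d.append(dist[s][t])
        paths = all_shortest_paths(adj, dist[s], s, t)
        sigma = len(paths)
        for u in nodes:
            if u in (s, t):
                continue
            through = sum(1 for p in paths if u in p)
            betweenness[u] += through / sigma
    diameter = max(pair_d) if pair_d else None
    apl = sum(pair_d) / len(pair_d) if pair_d else None
    return {
        "degree": degree,
        "closeness": closeness,
        "betweenness": betweenness,
        "diameter": diameter,
        "avg_path_length": apl,
    }


def _set_partitions(items):
    """All partitions of a list (restricted-growth recursion)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [[first] + block] + partition[i + 1 :]
        yield [[first]] + partition


def newman_q(edges, partition):
    """Newman modularity of a partition, straight from the definition."""
    m = len(edges)
    if m == 0:
        return float("nan")
    member = {}
    for c, block in enumerate(partition):
        for u in block:
            member[u] = c
    n_comm = len(partition)
    within = [0] * n_comm
    deg = [0] * n_comm
    for u, v in edges:
        deg[member[u]] += 1
        deg[member[v]] += 1
        if member[u] == member[v]:
            within[member[u]] += 1
    return sum(w / m - (d / (2 * m)) ** 2 for w, d in zip(within, deg))


def brute_max_modularity(edges, nodes):
    """Maximum Q over all partitions (feasible for <= 8 nodes)."""
    best_q, best_part = -np.inf, None
    for partition in _set_partitions(sorted(nodes)):
        q = newman_q(edges, partition)
        if q > best_q:
            best_q, best_part = q, partition
    return best_q, best_part


def random_connected_graph(rng, n_max=7):
    """Random connected simple graph with 2..n_max nodes."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        p = rng.uniform(0.25, 0.9)
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            (a, b) for a, b in combinations(nodes, 2) if rng.random() < p
        ]
        adj = adjacency(edges, nodes)
        if len(bfs_distances(adj, nodes[0])) == n:
            return nodes, edges


def hypergeometric_expected_richness(counts, depth):
    """Closed-form E[richness] via exact integer binomials."""
    total = sum(counts)
    out = 0.0
    for c in counts:
        if c == 0:
            continue
        if total - c >= depth:
            out += 1.0 - comb(total - c, depth) / comb(total, depth)
        else:
            out += 1.0
    return out
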